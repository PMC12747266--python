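"""ChEMBL-style bioactivity curation: validate, filter, deduplicate,
log-transform, split and rebalance IC50 activity tables.

The cleaning pipeline applies, in order: SMILES validation and
canonicalization (keeping the largest fragment of multi-fragment inputs),
removal of non-IC50 / non-numeric rows, unit harmonization to nanomolar
(nM and µM accepted), removal of non-positive concentrations, collapse of
duplicate (compound, target) measurements to their median, and a log10
transform. Every dropped row is accounted for in a provenance ledger so
that raw count = clean count + total drops always holds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

import numpy as np
import pandas as pd
from rdkit import Chem

RAW_COLUMNS = ("smiles", "target_chembl_id", "standard_value",
               "standard_units", "standard_type")

_UNIT_TO_NM = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "μm": 1000.0}


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    """One raw compound-target IC50 measurement, possibly invalid."""

    smiles: str
    target_id: str
    standard_value: object  # may be missing / non-numeric before cleaning
    standard_units: str
    standard_type: str = "IC50"


@dataclass(frozen=True)
class CleanSample:
    """One deduplicated (canonical SMILES, target, log10 IC50[nM]) unit."""

    canonical_smiles: str
    target_id: str
    log_ic50: float


@dataclass
class CleanDataset:
    samples: list[CleanSample]
    provenance: dict[str, int] = field(default_factory=dict)
    n_raw: int = 0
    n_multi_fragment: int = 0  # informational; these rows are kept

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_clean(self) -> int:
        return len(self.samples)

    def targets(self) -> list[str]:
        return sorted({s.target_id for s in self.samples})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.canonical_smiles, s.target_id, s.log_ic50)
             for s in self.samples],
            columns=["canonical_smiles", "target_id", "log_ic50"])

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(
            {"n_raw": self.n_raw, "n_clean": self.n_clean,
             "n_multi_fragment": self.n_multi_fragment,
             "dropped": self.provenance}, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "CleanDataset":
        df = pd.read_csv(csv_path)
        samples = [CleanSample(r.canonical_smiles, r.target_id, float(r.log_ic50))
                   for r in df.itertuples()]
        ds = cls(samples=samples, n_raw=len(samples))
        sidecar = Path(csv_path).with_suffix(".provenance.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            ds.n_raw = meta.get("n_raw", ds.n_raw)
            ds.provenance = meta.get("dropped", {})
            ds.n_multi_fragment = meta.get("n_multi_fragment", 0)
        return ds


@dataclass
class SplitDataset:
    train: CleanDataset
    test: CleanDataset
    seed: int


def canonicalize(smiles: str, keep_largest_fragment: bool = True) -> str:
    """Canonical SMILES via RDKit; identical molecules map to one string.

    Multi-fragment inputs (salts) are reduced to the largest fragment by
    heavy-atom count before canonicalization.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValidationError(f"invalid SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparsable SMILES: {smiles!r}")
    if keep_largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


def _is_multi_fragment(smiles: str) -> bool:
    return "." in smiles


def clean_activities(records: list[ActivityRecord]) -> CleanDataset:
    """Apply the quality filters in order; record per-stage drop counts.

    Stages: invalid_smiles -> bad_value_or_type -> bad_units ->
    nonpositive -> duplicate_collapsed (median over each
    (canonical_smiles, target) group, then log10 of IC50 in nM).
    """
    provenance = {"invalid_smiles": 0, "bad_value_or_type": 0,
                  "bad_units": 0, "nonpositive": 0, "duplicate_collapsed": 0}
    n_multi_fragment = 0
    groups: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []

    for rec in records:
        try:
            canonical = canonicalize(rec.smiles)
        except ValidationError:
            provenance["invalid_smiles"] += 1
            continue
        if isinstance(rec.smiles, str) and _is_multi_fragment(rec.smiles):
            n_multi_fragment += 1

        if str(rec.standard_type).strip().upper() != "IC50":
            provenance["bad_value_or_type"] += 1
            continue
        try:
            value = float(rec.standard_value)
        except (TypeError, ValueError):
            provenance["bad_value_or_type"] += 1
            continue
        if math.isnan(value):
            provenance["bad_value_or_type"] += 1
            continue

        unit = str(rec.standard_units).strip().lower()
        if unit not in _UNIT_TO_NM:
            provenance["bad_units"] += 1
            continue
        value_nm = value * _UNIT_TO_NM[unit]

        if value_nm <= 0:
            provenance["nonpositive"] += 1
            continue

        key = (canonical, str(rec.target_id))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(value_nm)

    samples = []
    for key in order:
        values = groups[key]
        provenance["duplicate_collapsed"] += len(values) - 1
        samples.append(CleanSample(
            canonical_smiles=key[0], target_id=key[1],
            log_ic50=math.log10(median(values))))

    return CleanDataset(samples=samples, provenance=provenance,
                        n_raw=len(records), n_multi_fragment=n_multi_fragment)


def load_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """Read a raw activity table (ChEMBL-export shaped CSV)."""
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    return [ActivityRecord(
        smiles=row.smiles if isinstance(row.smiles, str) else "",
        target_id=str(row.target_chembl_id),
        standard_value=row.standard_value,
        standard_units=str(row.standard_units),
        standard_type=str(row.standard_type),
    ) for row in df.itertuples()]


def split(dataset: CleanDataset, test_fraction: float = 0.2,
          seed: int = 42, by_compound: bool = False) -> SplitDataset:
    """Seeded uniform random train/test split.

    Record-level by default (a compound may appear in train for one target
    and in test for another — see the docs for the leakage caveat);
    ``by_compound=True`` keeps all records of a compound on one side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(dataset.samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    if by_compound:
        compounds = sorted({s.canonical_smiles for s in dataset.samples})
        perm = rng.permutation(len(compounds))
        n_train_c = int(round((1 - test_fraction) * len(compounds)))
        train_set = {compounds[i] for i in perm[:n_train_c]}
        train_idx = [i for i, s in enumerate(dataset.samples)
                     if s.canonical_smiles in train_set]
        test_idx = [i for i, s in enumerate(dataset.samples)
                    if s.canonical_smiles not in train_set]
    else:
        perm = rng.permutation(n)
        n_train = int(round((1 - test_fraction) * n))
        train_idx = sorted(perm[:n_train].tolist())
        test_idx = sorted(perm[n_train:].tolist())
    train = CleanDataset([dataset.samples[i] for i in train_idx],
                         n_raw=len(train_idx))
    test = CleanDataset([dataset.samples[i] for i in test_idx],
                        n_raw=len(test_idx))
    return SplitDataset(train=train, test=test, seed=seed)


def oversample_by_target(train: CleanDataset, seed: int = 42) -> CleanDataset:
    """Resample with replacement so every target matches the largest one.

    All original samples are retained; under-represented targets are padded
    with seeded draws from their own samples, then the whole set is shuffled
    with the same seed.
    """
    if not train.samples:
        raise ValueError("cannot oversample an empty dataset")
    rng = np.random.default_rng(seed)
    by_target: dict[str, list[CleanSample]] = {}
    for s in train.samples:
        by_target.setdefault(s.target_id, []).append(s)
    max_count = max(len(v) for v in by_target.values())
    out: list[CleanSample] = []
    for target in sorted(by_target):
        group = by_target[target]
        out.extend(group)
        deficit = max_count - len(group)
        if deficit > 0:
            extra_idx = rng.integers(0, len(group), size=deficit)
            out.extend(group[i] for i in extra_idx)
    perm = rng.permutation(len(out))
    return CleanDataset([out[i] for i in perm], n_raw=len(out))
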