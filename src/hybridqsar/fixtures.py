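"""Deterministic synthetic molecules and activity tables.

Molecules are assembled from a small fragment grammar (substituted benzene /
pyridine / furan / cyclohexane cores and short functionalized chains), which
guarantees chemical validity without rejection sampling while covering a
spread of ring counts, heteroatoms, flexibility and lipophilicity.

Activity tables plant a recoverable structure-activity signal:

* ``signal="descriptor"``: log10 IC50(nM) is a linear function of z-scored
  physicochemical descriptors plus a per-target offset and Gaussian noise —
  a signal the descriptor branch can provably recover;
* ``signal="substructure"``: activity shifts by a fixed amount when the
  molecule contains an aromatic nitrogen (pyridine-type ring) — a purely
  topological signal only the graph branch can see once descriptors are
  ablated (fingerprint bits are withheld from the label function either way).

Tables are emitted in the raw ChEMBL-export shape with mixed nM/µM units,
jittered duplicate measurements and (optionally) deliberately invalid rows,
so the cleaning pipeline is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .data_pipeline import RAW_COLUMNS
from .featurize import compute_physchem

CHEMBL_TARGETS = ("CHEMBL203", "CHEMBL204", "CHEMBL206", "CHEMBL332",
                  "CHEMBL1827", "CHEMBL2835", "CHEMBL2842", "CHEMBL4302",
                  "CHEMBL5763")

# single- and double-slot aromatic/aliphatic cores; {R} slots take substituents
_PLAIN_CORES = (
    "c1ccc({R})cc1",          # benzene
    "c1cc({R})oc1",           # furan
    "c1cc({R})sc1",           # thiophene
    "C1CCC({R})CC1",          # cyclohexane
    "C1CCC({R})C1",           # cyclopentane
    "c1ccc2cc({R})ccc2c1",    # naphthalene
    "c1cc({R})ccc1{R2}",      # 1,4-disubstituted benzene
    "c1cc({R})cc({R2})c1",    # 1,3-disubstituted benzene
    "C1CC({R})CC({R2})C1",    # disubstituted cyclohexane
    "c1cc({R})oc1{R2}",       # disubstituted furan
)
_PYRIDINE_CORES = (
    "c1ccc({R})nc1",          # pyridine
    "c1cc({R})ncn1",          # pyrimidine
    "c1cc({R})cnc1{R2}",      # disubstituted pyridine
    "c1nc({R})cc({R2})n1",    # disubstituted pyrimidine
)
_CHAINS = (
    "CC(N)C(=O)O", "CCCCO", "CC(C)CO", "CCOCC", "CC(=O)NC",
    "C[C@H](N)C(=O)O", "CC(O)CC", "NCCO", "CCCC(=O)O", "CC(C)(C)O",
    "CC({R})CC", "{R}CCOC", "CC(=O)N{R}", "CCC({R})CO",
)
_SUBSTITUENTS = ("C", "CC", "CCC", "CCO", "F", "Cl", "Br", "I", "O", "N",
                 "OC", "CO", "NC", "N(C)C", "C(C)C", "C(=O)O", "C#N",
                 "C(F)(F)F", "OC(=O)C", "CC(C)O", "S", "SC")

DEFAULT_SIGNAL_WEIGHTS = {
    "LogP": 0.6, "MolWt": 0.5, "TPSA": -0.4, "NumRotatableBonds": 0.3,
}


@dataclass
class FixtureSpec:
    """Conditions for one synthetic dataset.

    Defaults emulate the statistical shape of the curated multi-target
    IC50 data the pipeline expects: unequal target group sizes, activities
    spanning several orders of magnitude around the micromolar range, mixed
    nM/µM units, duplicate measurements and a small fraction of invalid rows.
    """

    n_molecules: int = 1000
    n_targets: int = 3
    target_size_ratios: tuple[float, ...] = (4.0, 2.0, 1.0)
    noise_sd: float = 0.3            # log10 units
    signal: str = "descriptor"       # or "substructure"
    signal_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_WEIGHTS))
    substructure_effect: float = 1.5  # log10 shift for aromatic-N molecules
    intercept: float = 3.0            # centers activities near 1 uM
    target_offset_step: float = 0.5
    seed: int = 7
    dirty_fraction: float = 0.05
    duplicate_fraction: float = 0.1
    um_fraction: float = 0.3

    def __post_init__(self):
        if self.n_targets > len(CHEMBL_TARGETS):
            raise ValueError("too many targets requested")
        if not 0 <= self.dirty_fraction < 1:
            raise ValueError("dirty_fraction must be in [0, 1)")
        ratios = tuple(self.target_size_ratios)[:self.n_targets]
        if len(ratios) < self.n_targets:
            ratios = ratios + (1.0,) * (self.n_targets - len(ratios))
        if any(r <= 0 for r in ratios):
            raise ValueError("target_size_ratios must be positive")
        self.target_size_ratios = ratios


def _sample_molecule(rng: np.random.Generator, signal: str) -> str:
    if signal == "substructure":
        # balance aromatic-N positives and negatives
        if rng.random() < 0.5:
            template = _PYRIDINE_CORES[rng.integers(len(_PYRIDINE_CORES))]
        else:
            pool = _PLAIN_CORES + (_CHAINS[rng.integers(len(_CHAINS))],)
            template = pool[rng.integers(len(pool))]
    else:
        pool = (_PLAIN_CORES + _PYRIDINE_CORES
                + (_CHAINS[rng.integers(len(_CHAINS))],))
        template = pool[rng.integers(len(pool))]
    smiles = template
    if "{R}" in smiles:
        smiles = smiles.replace(
            "{R}", _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))])
    if "{R2}" in smiles:
        smiles = smiles.replace(
            "{R2}", _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))])
    return smiles


def generate_molecules(spec: FixtureSpec) -> list[str]:
    """``n_molecules`` distinct, valid SMILES; deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > 100 * spec.n_molecules:
            raise RuntimeError("fragment grammar exhausted; lower n_molecules")
        smiles = _sample_molecule(rng, spec.signal)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar emits valid SMILES; guard regardless
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(smiles)
    return out


def _has_aromatic_nitrogen(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return any(a.GetSymbol() == "N" and a.GetIsAromatic()
               for a in mol.GetAtoms())


def planted_activities(spec: FixtureSpec, smiles_list: list[str]
                       ) -> np.ndarray:
    """Noise-free planted log10 IC50(nM) for each molecule (no target offset)."""
    if spec.signal == "substructure":
        flags = np.array([_has_aromatic_nitrogen(s) for s in smiles_list],
                         dtype=np.float64)
        return spec.intercept + spec.substructure_effect * flags
    names = list(spec.signal_weights)
    table = np.array([[compute_physchem(s)[n] for n in names]
                      for s in smiles_list])
    mu, sd = table.mean(axis=0), table.std(axis=0)
    z = (table - mu) / np.where(sd > 0, sd, 1.0)
    weights = np.array([spec.signal_weights[n] for n in names])
    return spec.intercept + z @ weights


def _assign_targets(spec: FixtureSpec, n: int,
                    rng: np.random.Generator) -> list[str]:
    ratios = np.asarray(spec.target_size_ratios, dtype=np.float64)
    counts = np.floor(n * ratios / ratios.sum()).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(ratios))] += 1
    labels = []
    for i, c in enumerate(counts):
        labels.extend([CHEMBL_TARGETS[i]] * c)
    rng.shuffle(labels)
    return labels


def generate_activity_table(spec: FixtureSpec) -> pd.DataFrame:
    """Raw activity rows (ChEMBL-export shape) with the planted signal.

    Base rows: one per molecule, with a target assignment following the
    size ratios and log-normal measurement noise. A ``duplicate_fraction``
    of compounds gains a second jittered measurement; ``dirty_fraction``
    of the base count is appended as deliberately invalid rows (malformed
    SMILES, non-positive values, missing units, wrong standard type).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    smiles_list = generate_molecules(spec)
    base = planted_activities(spec, smiles_list)
    targets = _assign_targets(spec, len(smiles_list), rng)
    offsets = {CHEMBL_TARGETS[i]: i * spec.target_offset_step
               for i in range(spec.n_targets)}

    rows: list[tuple] = []

    def emit(smiles: str, target: str, log_nm: float) -> None:
        value_nm = 10.0 ** log_nm
        if rng.random() < spec.um_fraction:
            rows.append((smiles, target, value_nm / 1000.0, "uM", "IC50"))
        else:
            rows.append((smiles, target, value_nm, "nM", "IC50"))

    for smiles, target, activity in zip(smiles_list, targets, base):
        log_nm = activity + offsets[target] + rng.normal(0, spec.noise_sd)
        emit(smiles, target, log_nm)
        if rng.random() < spec.duplicate_fraction:
            emit(smiles, target, log_nm + rng.normal(0, 0.1))

    n_dirty = int(round(spec.dirty_fraction * len(smiles_list)))
    dirty_kinds = ["bad_smiles", "nonpositive", "missing_units", "wrong_type"]
    for k in range(n_dirty):
        kind = dirty_kinds[k % len(dirty_kinds)]
        target = CHEMBL_TARGETS[int(rng.integers(spec.n_targets))]
        if kind == "bad_smiles":
            rows.append(("C1CC(", target, 100.0, "nM", "IC50"))
        elif kind == "nonpositive":
            value = 0.0 if k % 2 else -5.0
            rows.append(("CCO", target, value, "nM", "IC50"))
        elif kind == "missing_units":
            rows.append(("CCN", target, 100.0, "", "IC50"))
        else:
            rows.append(("CCC", target, 100.0, "nM", "Ki"))

    df = pd.DataFrame(rows, columns=list(RAW_COLUMNS))
    return df.sample(frac=1.0, random_state=int(
        rng.integers(2 ** 31))).reset_index(drop=True)
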