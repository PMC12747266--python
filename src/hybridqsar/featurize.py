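"""SMILES featurization: hybridization-explicit molecular graphs and
descriptor vectors.

Two complementary representations are produced for each molecule:

* a molecular graph whose node identities come from a joint
  (element, hybridization) vocabulary — sp3 and sp2 carbon are distinct node
  classes — with 11 per-atom features and 5 per-bond features on each
  directed edge;
* a 544-dimensional descriptor vector: 512-bit Morgan fingerprint (radius 2)
  concatenated after 32 physicochemical descriptors, z-score normalized with
  statistics fitted on the training set only.

All chemistry goes through RDKit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

NODE_FEATURE_NAMES = (
    "vocab_id", "atomic_number", "degree", "formal_charge", "total_h",
    "is_aromatic", "in_ring", "chirality_r", "chirality_s",
    "smallest_ring_size", "total_valence",
)
EDGE_FEATURE_NAMES = (
    "bond_type", "is_conjugated", "in_ring", "is_aromatic", "stereo",
)

N_NODE_FEATURES = len(NODE_FEATURE_NAMES)   # 11
N_EDGE_FEATURES = len(EDGE_FEATURE_NAMES)   # 5
N_FINGERPRINT_BITS = 512
N_PHYSCHEM = 32
N_DESCRIPTORS = N_FINGERPRINT_BITS + N_PHYSCHEM  # 544

DEFAULT_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
                    "Si", "Se")
DEFAULT_HYBRIDIZATIONS = ("S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "OTHER")

_BOND_TYPE_CODES = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 4.0,
}


class FeaturizationError(ValueError):
    """Raised when a SMILES cannot be parsed or a descriptor fails."""


@dataclass(frozen=True)
class AtomVocab:
    """Vocabulary over (element, hybridization) tuples plus an OOV bucket."""

    entries: tuple[tuple[str, str], ...]
    _index: dict[tuple[str, str], int] = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index",
                           {pair: i for i, pair in enumerate(self.entries)})

    @property
    def unknown_index(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries) + 1  # + unknown bucket

    def lookup(self, element: str, hybridization: str) -> int:
        return self._index.get((element, hybridization), self.unknown_index)

    def to_dict(self) -> dict:
        return {"entries": [list(e) for e in self.entries]}

    @classmethod
    def from_dict(cls, d: dict) -> "AtomVocab":
        return cls(entries=tuple(tuple(e) for e in d["entries"]))


def build_vocab(elements=DEFAULT_ELEMENTS,
                hybridizations=DEFAULT_HYBRIDIZATIONS) -> AtomVocab:
    """Cartesian-product vocabulary in deterministic order + unknown bucket."""
    if not elements or not hybridizations:
        raise ValueError("element and hybridization sets must be non-empty")
    if len(set(elements)) != len(elements):
        raise ValueError("duplicate element symbols")
    if len(set(hybridizations)) != len(hybridizations):
        raise ValueError("duplicate hybridization labels")
    entries = tuple((el, hy) for el in elements for hy in hybridizations)
    return AtomVocab(entries=entries)


def _hybridization_label(atom: Chem.Atom) -> str:
    name = str(atom.GetHybridization())
    return name if name in DEFAULT_HYBRIDIZATIONS else "OTHER"


@dataclass
class MolecularGraph:
    """Arrays describing one molecule as a directed graph (implicit H)."""

    n_nodes: int
    node_vocab_ids: np.ndarray          # (n_nodes,) int
    node_features: np.ndarray           # (n_nodes, 11) float
    edge_index: np.ndarray              # (2, n_edges) int, both directions
    edge_features: np.ndarray           # (n_edges, 5) float
    mol_size: int                       # sum of heavy-atom atomic numbers


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    return mol


def _smallest_ring_size(mol: Chem.Mol, atom_idx: int) -> int:
    info = mol.GetRingInfo()
    sizes = [len(ring) for ring in info.AtomRings() if atom_idx in ring]
    return min(sizes) if sizes else 0


def smiles_to_graph(smiles: str, vocab: AtomVocab) -> MolecularGraph:
    """Convert a SMILES into a :class:`MolecularGraph`.

    Hydrogens are implicit: they are not nodes but contribute to the per-atom
    total-H count. Each chemical bond yields two directed edges with
    identical features. Chirality flags come from CIP assignment; atoms
    without an assigned CIP code carry 0 in both flags.
    """
    mol = _mol_from_smiles(smiles)
    if mol.GetNumAtoms() == 0:
        raise FeaturizationError(f"no heavy atoms in {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    n = mol.GetNumAtoms()
    vocab_ids = np.zeros(n, dtype=np.int64)
    node_features = np.zeros((n, N_NODE_FEATURES))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        vid = vocab.lookup(atom.GetSymbol(), _hybridization_label(atom))
        cip = atom.GetPropsAsDict().get("_CIPCode", "")
        vocab_ids[i] = vid
        node_features[i] = [
            vid,
            atom.GetAtomicNum(),
            atom.GetDegree(),
            atom.GetFormalCharge(),
            atom.GetTotalNumHs(),
            float(atom.GetIsAromatic()),
            float(atom.IsInRing()),
            float(cip == "R"),
            float(cip == "S"),
            _smallest_ring_size(mol, i),
            atom.GetTotalValence(),
        ]

    srcs, dsts, feats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = [
            _BOND_TYPE_CODES.get(bond.GetBondType(), 0.0),
            float(bond.GetIsConjugated()),
            float(bond.IsInRing()),
            float(bond.GetIsAromatic()),
            float(int(bond.GetStereo())),
        ]
        srcs.extend([i, j])
        dsts.extend([j, i])
        feats.extend([f, f])

    edge_index = (np.array([srcs, dsts], dtype=np.int64) if srcs
                  else np.zeros((2, 0), dtype=np.int64))
    edge_features = (np.array(feats) if feats
                     else np.zeros((0, N_EDGE_FEATURES)))
    return MolecularGraph(
        n_nodes=n,
        node_vocab_ids=vocab_ids,
        node_features=node_features,
        edge_index=edge_index,
        edge_features=edge_features,
        mol_size=molecular_size(smiles),
    )


def molecular_size(smiles: str) -> int:
    """Sum of atomic numbers over heavy atoms (implicit hydrogens excluded)."""
    mol = _mol_from_smiles(smiles)
    return int(sum(a.GetAtomicNum() for a in mol.GetAtoms()))


# ---------------------------------------------------------------------------
# Physicochemical descriptor registry (32 descriptors, fixed order)
# ---------------------------------------------------------------------------

PHYSCHEM_REGISTRY: tuple[tuple[str, callable], ...] = (
    # lipophilicity / drug-likeness
    ("MolWt", Descriptors.MolWt),
    ("LogP", Crippen.MolLogP),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    # hydrogen bonding
    ("NumHDonors", rdMolDescriptors.CalcNumHBD),
    ("NumHAcceptors", rdMolDescriptors.CalcNumHBA),
    # structure
    ("NumRotatableBonds", rdMolDescriptors.CalcNumRotatableBonds),
    ("NumAromaticRings", rdMolDescriptors.CalcNumAromaticRings),
    ("NumAliphaticRings", rdMolDescriptors.CalcNumAliphaticRings),
    ("NumSaturatedRings", rdMolDescriptors.CalcNumSaturatedRings),
    ("RingCount", rdMolDescriptors.CalcNumRings),
    ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
    ("HeavyAtomCount", lambda m: float(m.GetNumHeavyAtoms())),
    ("NumStereocenters", rdMolDescriptors.CalcNumAtomStereoCenters),
    # electronic
    ("FormalCharge", lambda m: float(Chem.GetFormalCharge(m))),
    ("NumHeteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
    ("NumValenceElectrons", Descriptors.NumValenceElectrons),
    ("MolMR", Crippen.MolMR),
    # shape
    ("Kappa1", GraphDescriptors.Kappa1),
    ("Kappa2", GraphDescriptors.Kappa2),
    ("Kappa3", GraphDescriptors.Kappa3),
    # complexity
    ("BertzCT", GraphDescriptors.BertzCT),
    ("NumBridgeheadAtoms", rdMolDescriptors.CalcNumBridgeheadAtoms),
    ("NumSpiroAtoms", rdMolDescriptors.CalcNumSpiroAtoms),
    # additional standard descriptors filling the 32-slot registry
    ("HallKierAlpha", GraphDescriptors.HallKierAlpha),
    ("Chi0v", GraphDescriptors.Chi0v),
    ("Chi1v", GraphDescriptors.Chi1v),
    ("Chi2v", GraphDescriptors.Chi2v),
    ("LabuteASA", rdMolDescriptors.CalcLabuteASA),
    ("NHOHCount", Descriptors.NHOHCount),
    ("NOCount", Descriptors.NOCount),
    ("NumAromaticHeterocycles", rdMolDescriptors.CalcNumAromaticHeterocycles),
    ("NumAliphaticHeterocycles", rdMolDescriptors.CalcNumAliphaticHeterocycles),
)

PHYSCHEM_NAMES: tuple[str, ...] = tuple(name for name, _ in PHYSCHEM_REGISTRY)
assert len(PHYSCHEM_REGISTRY) == N_PHYSCHEM

_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=2, fpSize=N_FINGERPRINT_BITS)


def compute_physchem(smiles: str) -> dict[str, float]:
    """The 32 physicochemical descriptors, in registry order."""
    mol = _mol_from_smiles(smiles)
    values: dict[str, float] = {}
    for name, fn in PHYSCHEM_REGISTRY:
        try:
            values[name] = float(fn(mol))
        except Exception as exc:  # pragma: no cover - descriptor failure
            raise FeaturizationError(
                f"descriptor {name} failed on {smiles!r}: {exc}") from exc
    return values


def compute_fingerprint(smiles: str) -> np.ndarray:
    """512-bit Morgan (circular) fingerprint, radius 2, as a 0/1 vector."""
    mol = _mol_from_smiles(smiles)
    fp = _MORGAN_GEN.GetFingerprintAsNumPy(mol)
    return fp.astype(np.float64)


def descriptor_vector(smiles: str) -> np.ndarray:
    """Combined length-544 vector: [512 fingerprint bits | 32 physchem]."""
    fp = compute_fingerprint(smiles)
    pc = compute_physchem(smiles)
    vec = np.concatenate([fp, [pc[name] for name in PHYSCHEM_NAMES]])
    assert vec.shape == (N_DESCRIPTORS,)
    return vec


# ---------------------------------------------------------------------------
# Train-fitted z-score normalization
# ---------------------------------------------------------------------------

@dataclass
class Normalizer:
    """Per-dimension z-scoring with a zero-variance guard.

    Constant dimensions (std == 0, common for unused fingerprint bits on
    small training sets) map to exactly 0 after normalization.
    """

    means: np.ndarray
    stds: np.ndarray
    fitted_on: int
    eps: float = 1e-8

    def apply(self, vec: np.ndarray) -> np.ndarray:
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape[-1] != self.means.shape[0]:
            raise ValueError(
                f"expected width {self.means.shape[0]}, got {vec.shape[-1]}")
        out = (vec - self.means) / np.maximum(self.stds, self.eps)
        constant = self.stds == 0
        if vec.ndim == 1:
            out[constant] = 0.0
        else:
            out[:, constant] = 0.0
        return out

    def to_dict(self) -> dict:
        return {"means": self.means.tolist(), "stds": self.stds.tolist(),
                "fitted_on": self.fitted_on, "eps": self.eps}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(means=np.asarray(d["means"]), stds=np.asarray(d["stds"]),
                   fitted_on=int(d["fitted_on"]), eps=float(d.get("eps", 1e-8)))


def fit_normalizer(train_vectors: np.ndarray) -> Normalizer:
    """Fit per-dimension mean/std (population std) on training vectors only."""
    x = np.asarray(train_vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit a normalizer")
    return Normalizer(means=x.mean(axis=0), stds=x.std(axis=0),
                      fitted_on=x.shape[0])
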