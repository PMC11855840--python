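"""Dataset parsing, curation, labeling, splitting, and molecular-graph building.

The activity task is binary classification of BACE-1 inhibitors: a compound
is active when its log10 IC50 (IC50 in nM) is below 2, i.e. IC50 < 100 nM.

Graph featurization follows the widely used 133/14 convention for
message-passing networks on molecules: every categorical atom/bond property
is one-hot encoded with a trailing "other" slot, plus scalar mass.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

ATOM_FDIM = 133
BOND_FDIM = 14

ACTIVITY_LOG_IC50_THRESHOLD = 2.0  # log10(nM); 100 nM

__all__ = [
    "ATOM_FDIM",
    "BOND_FDIM",
    "ACTIVITY_LOG_IC50_THRESHOLD",
    "MoleculeRecord",
    "MolGraph",
    "DatasetSplit",
    "build_mol_graph",
    "curate_dataset",
    "binarize_label",
    "split_dataset",
    "load_dataset_csv",
    "records_to_frame",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One labeled compound."""

    smiles: str
    log_ic50: float
    label: int
    id: str

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")


@dataclass
class MolGraph:
    """Featurized molecular graph.

    ``edges`` stores both directions of every bond (2*n_bonds pairs) for
    message passing; ``bond_features`` has one row per *undirected* bond,
    and ``edge_to_bond[e]`` maps a directed edge to its bond row.
    """

    atom_features: np.ndarray  # [N_V, 133]
    bond_features: np.ndarray  # [N_E, 14]
    edges: list[tuple[int, int]]  # directed, length 2*N_E
    edge_to_bond: np.ndarray  # [2*N_E]
    n_atoms: int
    n_bonds: int


@dataclass
class DatasetSplit:
    train: list[MoleculeRecord]
    validation: list[MoleculeRecord]
    test: list[MoleculeRecord]
    seed: int
    ratios: tuple[float, float, float]

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "ratios": list(self.ratios),
            "train": [r.id for r in self.train],
            "validation": [r.id for r in self.validation],
            "test": [r.id for r in self.test],
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

_ATOMIC_NUMS = list(range(1, 101))  # first 100 elements
_DEGREES = [0, 1, 2, 3, 4, 5]
_FORMAL_CHARGES = [-1, -2, 1, 2, 0]
_CHIRAL_TAGS = [0, 1, 2, 3]
_NUM_HS = [0, 1, 2, 3, 4]
_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]
_BOND_STEREO = [0, 1, 2, 3, 4, 5]


def _onehot_other(value, choices: list) -> list[float]:
    """One-hot over `choices` plus a trailing slot for anything else."""
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_feature_vector(atom: Chem.Atom) -> np.ndarray:
    feats = (
        _onehot_other(atom.GetAtomicNum(), _ATOMIC_NUMS)
        + _onehot_other(atom.GetTotalDegree(), _DEGREES)
        + _onehot_other(atom.GetFormalCharge(), _FORMAL_CHARGES)
        + _onehot_other(int(atom.GetChiralTag()), _CHIRAL_TAGS)
        + _onehot_other(atom.GetTotalNumHs(), _NUM_HS)
        + _onehot_other(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() / 100.0]
    )
    return np.asarray(feats)


def bond_feature_vector(bond: Chem.Bond) -> np.ndarray:
    bt = bond.GetBondType()
    feats = [
        0.0,  # null-bond flag (set only for absent bonds)
        1.0 if bt == Chem.rdchem.BondType.SINGLE else 0.0,
        1.0 if bt == Chem.rdchem.BondType.DOUBLE else 0.0,
        1.0 if bt == Chem.rdchem.BondType.TRIPLE else 0.0,
        1.0 if bt == Chem.rdchem.BondType.AROMATIC else 0.0,
        1.0 if bond.GetIsConjugated() else 0.0,
        1.0 if bond.IsInRing() else 0.0,
    ] + _onehot_other(int(bond.GetStereo()), _BOND_STEREO)
    return np.asarray(feats)


class SmilesParseError(ValueError):
    pass


class EmptyMoleculeError(ValueError):
    pass


def _parse(smiles: str) -> Chem.Mol:
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def build_mol_graph(smiles: str) -> MolGraph:
    """Build the featurized graph of a molecule from its SMILES.

    Atoms keep RDKit parser order, so the result is deterministic for a
    given input string.
    """
    mol = _parse(smiles)
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        raise EmptyMoleculeError(f"molecule has no atoms: {smiles!r}")
    atom_feats = np.stack([atom_feature_vector(a) for a in mol.GetAtoms()])
    bonds = list(mol.GetBonds())
    n_bonds = len(bonds)
    if n_bonds:
        bond_feats = np.stack([bond_feature_vector(b) for b in bonds])
    else:
        bond_feats = np.zeros((0, BOND_FDIM))
    edges: list[tuple[int, int]] = []
    edge_to_bond: list[int] = []
    for bi, bond in enumerate(bonds):
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((u, v))
        edges.append((v, u))
        edge_to_bond.extend([bi, bi])
    assert atom_feats.shape == (n_atoms, ATOM_FDIM)
    assert bond_feats.shape == (n_bonds, BOND_FDIM)
    return MolGraph(
        atom_features=atom_feats,
        bond_features=bond_feats,
        edges=edges,
        edge_to_bond=np.asarray(edge_to_bond, dtype=np.int64),
        n_atoms=n_atoms,
        n_bonds=n_bonds,
    )


# ---------------------------------------------------------------------------
# curation and labeling
# ---------------------------------------------------------------------------

def binarize_label(log_ic50: float) -> int:
    """Active (1) iff log10 IC50[nM] is strictly below 2; exactly 2 is inactive."""
    if log_ic50 is None or (isinstance(log_ic50, float) and math.isnan(log_ic50)):
        raise ValueError("log_ic50 is NaN/None; cannot binarize")
    return 1 if float(log_ic50) < ACTIVITY_LOG_IC50_THRESHOLD else 0


def _extract_log_ic50(raw: Mapping) -> float | None:
    if raw.get("log_ic50") is not None:
        try:
            v = float(raw["log_ic50"])
        except (TypeError, ValueError):
            return None
        return v if math.isfinite(v) else None
    if raw.get("ic50_nm") is not None:
        try:
            v = float(raw["ic50_nm"])
        except (TypeError, ValueError):
            return None
        if not math.isfinite(v) or v <= 0:
            return None
        return math.log10(v)
    return None


def curate_dataset(records: Iterable[Mapping]) -> list[MoleculeRecord]:
    """Clean raw records into labeled :class:`MoleculeRecord` objects.

    Drops (with a logged reason): multi-component/salt SMILES (containing
    "."), unparseable SMILES, records without a conclusive numeric IC50,
    and duplicate structures (same canonical SMILES; first kept).
    Idempotent: re-curating the output is a no-op.
    """
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for i, raw in enumerate(records):
        if isinstance(raw, MoleculeRecord):
            raw = {"smiles": raw.smiles, "log_ic50": raw.log_ic50, "id": raw.id}
        smiles = str(raw.get("smiles", "") or "")
        rid = str(raw.get("id", i))
        if "." in smiles:
            logger.info("drop %s: multi-component (salt) SMILES", rid)
            continue
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumAtoms() == 0:
            logger.info("drop %s: unparseable SMILES %r", rid, smiles)
            continue
        log_ic50 = _extract_log_ic50(raw)
        if log_ic50 is None:
            logger.info("drop %s: inconclusive/non-numeric IC50", rid)
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            logger.info("drop %s: duplicate structure %s", rid, canonical)
            continue
        seen.add(canonical)
        out.append(
            MoleculeRecord(
                smiles=smiles,
                log_ic50=log_ic50,
                label=binarize_label(log_ic50),
                id=rid,
            )
        )
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _allocate_per_class(n_take: int, class_sizes: dict, n_total: int) -> dict:
    """Largest-remainder allocation of `n_take` slots across classes."""
    base = {}
    fracs = []
    for c, n_c in sorted(class_sizes.items()):
        exact = n_take * n_c / n_total
        base[c] = int(math.floor(exact))
        fracs.append((exact - base[c], c))
    short = n_take - sum(base.values())
    for _, c in sorted(fracs, key=lambda t: (-t[0], t[1]))[:short]:
        base[c] += 1
    return base


def split_dataset(
    records: Sequence[MoleculeRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic stratified train/validation/test split.

    Validation and test get exactly floor(ratio*N) records each; the
    remainder goes to train.  Within each target size, records are drawn
    proportionally from both label classes (largest-remainder rounding),
    keeping per-split class ratios close to the global one.
    """
    records = list(records)
    N = len(records)
    if N < 10:
        raise ValueError("need at least 10 records to split")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    n_val = int(math.floor(ratios[1] * N))
    n_test = int(math.floor(ratios[2] * N))
    if n_val == 0 or n_test == 0:
        raise ValueError("a split with non-zero ratio would be empty")

    rng = np.random.default_rng(seed)
    by_class: dict[int, list[MoleculeRecord]] = {}
    for r in records:
        by_class.setdefault(r.label, []).append(r)
    for c in by_class:
        order = rng.permutation(len(by_class[c]))
        by_class[c] = [by_class[c][i] for i in order]

    class_sizes = {c: len(v) for c, v in by_class.items()}
    take_test = _allocate_per_class(n_test, class_sizes, N)
    remaining = {c: class_sizes[c] - take_test[c] for c in class_sizes}
    take_val = _allocate_per_class(n_val, remaining, N - n_test)

    test, val, train = [], [], []
    for c in sorted(by_class):
        pool = by_class[c]
        test.extend(pool[: take_test[c]])
        val.extend(pool[take_test[c]: take_test[c] + take_val[c]])
        train.extend(pool[take_test[c] + take_val[c]:])
    return DatasetSplit(train=train, validation=val, test=test, seed=seed,
                        ratios=tuple(ratios))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_dataset_csv(path) -> list[dict]:
    """Read a UTF-8 CSV with required column `smiles` and `ic50_nm` or
    `log_ic50` into raw record dicts suitable for :func:`curate_dataset`."""
    df = pd.read_csv(path, dtype={"smiles": str})
    if "smiles" not in df.columns:
        raise ValueError("CSV must have a 'smiles' column")
    if "ic50_nm" not in df.columns and "log_ic50" not in df.columns:
        raise ValueError("CSV must have an 'ic50_nm' or 'log_ic50' column")
    recs = df.to_dict(orient="records")
    for i, r in enumerate(recs):
        r.setdefault("id", str(i))
    return recs


def records_to_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "log_ic50": [r.log_ic50 for r in records],
            "label": [r.label for r in records],
        }
    )
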