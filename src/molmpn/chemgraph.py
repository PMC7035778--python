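"""Chemical-graph construction and featurization.

A molecule is represented as a directed graph over its heavy atoms: every
chemical bond contributes two opposed directed edges, so the number of
directed edges is always twice the number of bonds.  Four index lists tie
the graph together (edge source/target nodes, the incoming-edge list of
every node, and the reverse-edge involution); the message passing encoder
consumes exactly these lists.

Atom and bond feature vectors are fixed-layout one-hot blocks:

==============  ======================================================  ====
block           encoding                                                size
==============  ======================================================  ====
atom type       one-hot over atomic number 1..118                        118
degree          heavy-atom neighbour count, buckets 0..5                   6
formal charge   one-hot over {-2, -1, 0, +1, +2}                           5
chirality       R, S, unspecified, unrecognized                            4
hybridization   sp, sp2, sp3, sp3d, sp3d2                                  5
aromaticity     single binary flag                                         1
--------------  ------------------------------------------------------  ----
bond type       single, double, triple, aromatic                           4
ring            bond is in a ring                                          1
stereo          none, any, Z, E, cis, trans                                6
==============  ======================================================  ====

giving 139 atom features and 11 bond features (150 when concatenated into
the per-edge input of the encoder).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

log = logging.getLogger(__name__)

N_ATOM_TYPES = 118
DEGREES = (0, 1, 2, 3, 4, 5)
FORMAL_CHARGES = (-2, -1, 0, 1, 2)
CHIRALITIES = ("R", "S", "unspecified", "unrecognized")
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
BOND_STEREOS = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
)

ATOM_FDIM = N_ATOM_TYPES + len(DEGREES) + len(FORMAL_CHARGES) + len(CHIRALITIES) + len(HYBRIDIZATIONS) + 1
BOND_FDIM = len(BOND_TYPES) + 1 + len(BOND_STEREOS)
EDGE_FDIM = ATOM_FDIM + BOND_FDIM


# ---------------------------------------------------------------------------
# dataset records


@dataclasses.dataclass
class DatasetRecord:
    """One molecule with (possibly partially observed) regression targets.

    ``targets[k]`` is meaningful only where ``mask[k]`` is True; targets live
    on the property's own log scale (logP, log mol/L, ...), unitless here.
    """

    smiles: str
    targets: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float).reshape(-1)
        self.mask = np.asarray(self.mask, dtype=bool).reshape(-1)
        if self.targets.shape != self.mask.shape:
            raise ValueError("targets and mask must have equal length")


def read_dataset(path, value_columns: Sequence[str] | None = None) -> list[DatasetRecord]:
    """Read a CSV with a 'smiles' column plus one or more numeric value columns.

    Blank cells become unobserved targets (``mask`` False).  If
    *value_columns* is None every non-smiles column is treated as a target.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if "smiles" not in df.columns:
        raise ValueError(f"{path}: required column 'smiles' is missing")
    if value_columns is None:
        value_columns = [c for c in df.columns if c != "smiles"]
    missing = [c for c in value_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: value column(s) {missing} not present")
    records = []
    for _, row in df.iterrows():
        vals = np.array([row[c] for c in value_columns], dtype=float)
        mask = ~np.isnan(vals)
        records.append(DatasetRecord(str(row["smiles"]), np.nan_to_num(vals), mask))
    return records


def write_dataset(records: Sequence[DatasetRecord], path, value_columns: Sequence[str] | None = None) -> None:
    """Write records back to the same CSV schema (blank cell = missing)."""
    k = len(records[0].targets) if records else 1
    if value_columns is None:
        value_columns = [f"value_{i}" for i in range(k)] if k > 1 else ["value"]
    rows = []
    for r in records:
        row = {"smiles": r.smiles}
        for i, c in enumerate(value_columns):
            row[c] = r.targets[i] if r.mask[i] else np.nan
        rows.append(row)
    pd.DataFrame(rows, columns=["smiles", *value_columns]).to_csv(path, index=False)


def clean_dataset(records: Sequence[DatasetRecord]) -> list[DatasetRecord]:
    """Drop unparseable SMILES and collapse duplicate structures.

    Duplicates are detected on canonical structure identity, not raw string
    equality.  When a structure occurs more than once, the maximum observed
    value of each property is kept (masks are OR-ed).  Output keeps
    first-occurrence order and carries the canonical SMILES.
    """
    by_canonical: dict[str, DatasetRecord] = {}
    order: list[str] = []
    n_dropped = 0
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            log.warning("dropping unparseable SMILES: %r", rec.smiles)
            n_dropped += 1
            continue
        can = Chem.MolToSmiles(mol)
        if can not in by_canonical:
            by_canonical[can] = DatasetRecord(can, rec.targets.copy(), rec.mask.copy())
            order.append(can)
        else:
            kept = by_canonical[can]
            both = kept.mask & rec.mask
            kept.targets[both] = np.maximum(kept.targets[both], rec.targets[both])
            new = rec.mask & ~kept.mask
            kept.targets[new] = rec.targets[new]
            kept.mask |= rec.mask
    if n_dropped:
        log.info("clean_dataset: dropped %d unparseable record(s)", n_dropped)
    return [by_canonical[c] for c in order]


# ---------------------------------------------------------------------------
# featurization


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    if 0 <= index < size:
        v[index] = 1.0
    return v


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """Binary feature vector (length 139) for one heavy atom."""
    z = atom.GetAtomicNum()
    if not 1 <= z <= N_ATOM_TYPES:
        raise ValueError(f"atomic number {z} outside 1..{N_ATOM_TYPES}")
    degree = atom.GetDegree()
    if degree > DEGREES[-1]:
        warnings.warn(f"heavy-neighbor count {degree} clamped to {DEGREES[-1]}", stacklevel=2)
        degree = DEGREES[-1]
    charge = atom.GetFormalCharge()
    if charge not in FORMAL_CHARGES:
        warnings.warn(f"formal charge {charge} clamped into {FORMAL_CHARGES}", stacklevel=2)
        charge = max(min(charge, FORMAL_CHARGES[-1]), FORMAL_CHARGES[0])
    if atom.HasProp("_CIPCode"):
        chirality = atom.GetProp("_CIPCode")  # 'R' or 'S'
    elif atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
        chirality = "unrecognized"
    else:
        chirality = "unspecified"
    hyb = atom.GetHybridization()
    hyb_idx = HYBRIDIZATIONS.index(hyb) if hyb in HYBRIDIZATIONS else -1
    return np.concatenate([
        _one_hot(z - 1, N_ATOM_TYPES),
        _one_hot(degree, len(DEGREES)),
        _one_hot(FORMAL_CHARGES.index(charge), len(FORMAL_CHARGES)),
        _one_hot(CHIRALITIES.index(chirality), len(CHIRALITIES)),
        _one_hot(hyb_idx, len(HYBRIDIZATIONS)),
        np.array([1.0 if atom.GetIsAromatic() else 0.0]),
    ])


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """Binary feature vector (length 11) for one bond."""
    btype = bond.GetBondType()
    if btype not in BOND_TYPES:
        raise ValueError(f"unsupported bond order {btype}")
    stereo = bond.GetStereo()
    if stereo not in BOND_STEREOS:
        log.warning("unknown bond stereo %s mapped to STEREONONE", stereo)
        stereo = Chem.BondStereo.STEREONONE
    return np.concatenate([
        _one_hot(BOND_TYPES.index(btype), len(BOND_TYPES)),
        np.array([1.0 if bond.IsInRing() else 0.0]),
        _one_hot(BOND_STEREOS.index(stereo), len(BOND_STEREOS)),
    ])


# ---------------------------------------------------------------------------
# graphs


@dataclasses.dataclass
class MolGraph:
    """Directed-edge graph of one molecule.

    ``edge_source``/``edge_target`` map each directed edge to its endpoint
    node indices; ``node2edge[y]`` lists the edges *incoming* to node ``y``
    (the direction the final aggregation needs); ``edge2revedge`` is the
    fixed-point-free involution pairing each edge with its reverse; and
    ``node2neinode[x]`` lists the neighbour nodes of ``x``.
    """

    n_atoms: int
    n_bonds: int
    atom_features: np.ndarray       # (n_atoms, 139)
    edge_features: np.ndarray       # (2*n_bonds, 11)
    edge_source: np.ndarray         # (2*n_bonds,)
    edge_target: np.ndarray         # (2*n_bonds,)
    node2edge: tuple                # per node: incoming directed-edge indices
    edge2revedge: np.ndarray        # (2*n_bonds,)
    node2neinode: tuple             # per node: neighbour node indices

    @property
    def n_edges(self) -> int:
        return 2 * self.n_bonds

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif isinstance(v, tuple):
                d[k] = [list(map(int, x)) for x in v]
        return json.dumps(d)


def mol_to_graph(smiles: str) -> MolGraph:
    """Parse a SMILES string into its directed heavy-atom graph.

    Hydrogens stay implicit; each bond yields a pair of opposed directed
    edges stored adjacently (edge 2i reversed by edge 2i+1).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES not parseable: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    n_atoms = mol.GetNumAtoms()
    n_bonds = mol.GetNumBonds()
    atom_features = np.array([featurize_atom(a) for a in mol.GetAtoms()]).reshape(n_atoms, ATOM_FDIM)

    edge_source, edge_target, edge_features = [], [], []
    incoming: list[list[int]] = [[] for _ in range(n_atoms)]
    neighbours: list[list[int]] = [[] for _ in range(n_atoms)]
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        for src, dst in ((a, b), (b, a)):
            e = len(edge_source)
            edge_source.append(src)
            edge_target.append(dst)
            edge_features.append(f)
            incoming[dst].append(e)
            neighbours[src].append(dst)
    e = np.arange(2 * n_bonds)
    return MolGraph(
        n_atoms=n_atoms,
        n_bonds=n_bonds,
        atom_features=atom_features,
        edge_features=np.array(edge_features).reshape(2 * n_bonds, BOND_FDIM),
        edge_source=np.array(edge_source, dtype=np.int64),
        edge_target=np.array(edge_target, dtype=np.int64),
        node2edge=tuple(tuple(x) for x in incoming),
        edge2revedge=e ^ 1,
        node2neinode=tuple(tuple(x) for x in neighbours),
    )


@dataclasses.dataclass
class BatchedGraph:
    """Several molecule graphs concatenated with per-molecule offsets.

    Atom and edge indices are shifted so molecule blocks never overlap;
    ``atom_scope``/``edge_scope`` hold (start, count) per molecule.
    """

    n_mols: int
    atom_features: np.ndarray
    edge_features: np.ndarray
    edge_source: np.ndarray
    edge_target: np.ndarray
    edge2revedge: np.ndarray
    atom_scope: tuple               # per molecule (start, n_atoms)
    edge_scope: tuple               # per molecule (start, n_edges)
    graphs: tuple                   # original MolGraphs, for unbatching

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_source.shape[0]


def batch_graphs(graphs: Sequence[MolGraph]) -> BatchedGraph:
    """Concatenate graphs into one disconnected graph (exact round trip)."""
    if not graphs:
        raise ValueError("batch_graphs requires a nonempty list")
    atom_scope, edge_scope = [], []
    src, dst, rev = [], [], []
    a_off = e_off = 0
    for g in graphs:
        atom_scope.append((a_off, g.n_atoms))
        edge_scope.append((e_off, g.n_edges))
        src.append(g.edge_source + a_off)
        dst.append(g.edge_target + a_off)
        rev.append(g.edge2revedge + e_off)
        a_off += g.n_atoms
        e_off += g.n_edges
    return BatchedGraph(
        n_mols=len(graphs),
        atom_features=np.concatenate([g.atom_features for g in graphs], axis=0),
        edge_features=(
            np.concatenate([g.edge_features for g in graphs], axis=0)
            if e_off else np.zeros((0, BOND_FDIM))
        ),
        edge_source=np.concatenate(src) if src else np.zeros(0, dtype=np.int64),
        edge_target=np.concatenate(dst) if dst else np.zeros(0, dtype=np.int64),
        edge2revedge=np.concatenate(rev) if rev else np.zeros(0, dtype=np.int64),
        atom_scope=tuple(atom_scope),
        edge_scope=tuple(edge_scope),
        graphs=tuple(graphs),
    )


def unbatch_graphs(batch: BatchedGraph) -> list[MolGraph]:
    return list(batch.graphs)
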