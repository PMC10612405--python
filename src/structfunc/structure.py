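"""Residue chains and contact graphs.

A protein structure is reduced to its ordered residues (one-letter amino
acid code + Cα coordinate, optionally all heavy-atom coordinates).  Two
residues are in contact when their Cα–Cα distance (or, in ``any_any`` mode,
their minimum pairwise atom distance) is strictly below a threshold,
10 Å by default.  The resulting undirected graph — nodes indexed 0..N-1 in
chain order — is the input of every downstream structural computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

#: canonical one-letter amino acid codes (X = unknown)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS) | {"X"}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


@dataclass
class Residue:
    amino_acid: str
    ca_coord: np.ndarray                      # shape (3,), Å
    atom_coords: np.ndarray | None = None     # shape (n_atoms, 3), Å


@dataclass
class ResidueChain:
    """Ordered residues of a single protein chain."""

    protein_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError(
                f"{self.protein_id}: a chain needs at least 2 residues, "
                f"got {len(self.residues)}"
            )
        for i, r in enumerate(self.residues):
            r.ca_coord = np.asarray(r.ca_coord, dtype=float)
            if r.ca_coord.shape != (3,) or not np.all(np.isfinite(r.ca_coord)):
                raise ValueError(f"{self.protein_id}: residue {i} has a bad Cα coordinate")
            if r.amino_acid not in _AA_SET:
                raise ValueError(f"{self.protein_id}: unknown amino acid {r.amino_acid!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in chain order."""
        return np.stack([r.ca_coord for r in self.residues])


@dataclass
class ContactGraph:
    """Undirected residue contact graph.

    Edges are stored once as sorted (i, j) pairs with i < j; self-loops are
    never stored (graph convolution adds its own self-connections).
    """

    protein_id: str
    n_nodes: int
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        clean = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"{self.protein_id}: self-edge ({i},{j}) not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"{self.protein_id}: edge ({i},{j}) out of range")
            clean.add((min(i, j), max(i, j)))
        self.edges = clean
        self._adj: list[list[int]] | None = None

    @property
    def node_order(self) -> list[int]:
        return list(range(self.n_nodes))

    def neighbors(self, v: int) -> list[int]:
        if self._adj is None:
            adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, j in sorted(self.edges):
                adj[i].append(j)
                adj[j].append(i)
            for lst in adj:
                lst.sort()
            self._adj = adj
        return self._adj[v]

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency, no self-loops."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def subgraph(self, nodes: list[int]) -> "ContactGraph":
        """Induced subgraph; new node t corresponds to old nodes[t]."""
        pos = {v: t for t, v in enumerate(nodes)}
        sub = {
            (pos[i], pos[j])
            for i, j in self.edges
            if i in pos and j in pos
        }
        return ContactGraph(self.protein_id, len(nodes), sub)


def read_structure(path: str | Path, format: str | None = None,
                   chain: str | None = None) -> ResidueChain:
    """Read a PDB or mmCIF file into a :class:`ResidueChain`.

    The first model is used; alternate locations prefer altloc 'A'.
    Residues without a Cα atom are skipped with a warning.

    Parameters
    ----------
    path:
        Structure file.  ``format`` is inferred from the suffix when not
        given ('.cif'/'.mmcif' → mmCIF, anything else → PDB).
    chain:
        Chain identifier; default is the first chain of the first model.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb")
    if fmt == "mmcif":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    elif fmt == "pdb":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = model[chain]
    residues: list[Residue] = []
    for res in ch:
        if res.is_water():
            continue
        ca = None
        atoms = []
        for atom in res:
            if atom.altloc not in ("\0", "", " ", "A"):
                continue
            xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            atoms.append(xyz)
            if atom.name == "CA":
                ca = xyz
        if ca is None:
            log.warning("%s: residue %s %s lacks a CA atom, skipping",
                        path.name, res.seqid.num, res.name)
            continue
        aa = _THREE_TO_ONE.get(res.name, "X")
        residues.append(Residue(aa, ca, np.stack(atoms) if atoms else None))
    if not residues:
        raise ValueError(f"{path}: no usable residues")
    return ResidueChain(path.stem, residues)


def write_pdb(chain: ResidueChain, path: str | Path) -> None:
    """Write Cα-only ATOM records (fixture/export helper)."""
    lines = []
    for i, r in enumerate(chain.residues):
        x, y, z = r.ca_coord
        name3 = _ONE_TO_THREE[r.amino_acid]
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {name3} A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def build_contact_map(chain: ResidueChain, threshold_angstrom: float = 10.0,
                      mode: str = "ca_ca", min_sequence_separation: int = 0,
                      ) -> ContactGraph:
    """Threshold pairwise residue distances into a contact graph.

    An edge (i, j), i ≠ j, is present iff the residue distance is
    *strictly* less than ``threshold_angstrom``.  ``mode='ca_ca'`` uses
    Cα–Cα distances; ``mode='any_any'`` the minimum over all atom pairs
    (requires atom_coords).  ``min_sequence_separation=w`` drops contacts
    with |i − j| ≤ w (default 0: sequential neighbours kept).
    """
    if threshold_angstrom <= 0:
        raise ValueError("threshold must be positive")
    n = len(chain)
    if mode == "ca_ca":
        d = cdist(chain.ca_coords(), chain.ca_coords())
    elif mode == "any_any":
        if any(r.atom_coords is None for r in chain.residues):
            raise ValueError(
                "any_any mode needs atom_coords for every residue; "
                "use mode='ca_ca' for Cα-only chains"
            )
        d = np.full((n, n), np.inf)
        for i in range(n):
            for j in range(i + 1, n):
                m = cdist(chain.residues[i].atom_coords,
                          chain.residues[j].atom_coords).min()
                d[i, j] = d[j, i] = m
    elif mode == "nbr":
        raise ValueError(
            "the NBR contact-map construction is not implemented "
            "(no public definition); use 'ca_ca' or 'any_any'"
        )
    else:
        raise ValueError(f"unknown contact mode {mode!r}")
    ii, jj = np.where(np.triu(d < threshold_angstrom, k=1))
    edges = {
        (int(i), int(j))
        for i, j in zip(ii, jj)
        if abs(int(i) - int(j)) > min_sequence_separation
    }
    return ContactGraph(chain.protein_id, n, edges)


def contact_density(graph: ContactGraph) -> float:
    """Fraction of possible residue pairs in contact, in [0, 1]."""
    if graph.n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return len(graph.edges) / (graph.n_nodes * (graph.n_nodes - 1) / 2)


def write_edge_list(graph: ContactGraph, path: str | Path) -> None:
    """Persist as TSV: header line `# n_nodes=<N>` then one `i\\tj` per edge."""
    with open(path, "w") as fh:
        fh.write(f"# protein_id={graph.protein_id}\tn_nodes={graph.n_nodes}\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path: str | Path) -> ContactGraph:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split("\t"))
        edges = set()
        for line in fh:
            i, j = line.split()
            edges.add((int(i), int(j)))
    return ContactGraph(meta.get("protein_id", path.stem), int(meta["n_nodes"]), edges)
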