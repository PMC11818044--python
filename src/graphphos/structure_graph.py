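"""Residue coordinates, distance matrices and the Cbeta contact graph.

A protein's tertiary structure is reduced to one representative point per
residue — the beta-carbon, or the alpha-carbon when no Cbeta exists
(glycine, incomplete side chains).  Two residues are *in contact* when
their representative atoms lie within 8 angstroms (inclusive), which turns
each structure into an undirected, unweighted residue graph whose node
index equals the sequence index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_THRESHOLD = 8.0  # angstroms, inclusive

#: sentinel distance for residues with no coordinates
MISSING_DISTANCE = np.inf


class ChainNotFoundError(KeyError):
    """Requested chain id absent from the structure."""


class EmptyChainError(ValueError):
    """Selected chain contains no polymer residues."""


@dataclass
class ResidueCoordinates:
    """Per-residue representative-atom coordinates for one chain.

    ``coords`` is an (L, 3) float array; rows of NaN mark residues with no
    usable atom.  ``plddt`` carries AlphaFold's per-residue confidence
    (read from the B-factor column) when the source was flagged as a
    predicted model.
    """

    protein_id: str
    coords: np.ndarray
    residue_names: list[str] = field(default_factory=list)
    plddt: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (L, 3), got {self.coords.shape}")
        present = ~self.missing_mask()
        if not np.all(np.isfinite(self.coords[present])):
            raise ValueError("present coordinates must be finite in all 3 components")
        if self.residue_names and len(self.residue_names) != len(self):
            raise ValueError("residue_names length does not match coords")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=np.float64)
            if self.plddt.shape != (len(self),):
                raise ValueError("plddt length does not match coords")
            if np.any((self.plddt < 0) | (self.plddt > 100)):
                raise ValueError("plddt values must lie in [0, 100]")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of residues lacking any representative atom."""
        return np.isnan(self.coords).any(axis=1)


@dataclass(frozen=True)
class ContactGraph:
    """Symmetric unweighted residue-residue adjacency.

    Edges are unordered 0-based index pairs stored as (i, j) with i < j,
    so symmetry holds by construction and self-loops are unrepresentable.
    """

    n_nodes: int
    edges: frozenset

    def __post_init__(self):
        for i, j in self.edges:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"edge ({i}, {j}) out of range for {self.n_nodes} nodes")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [sorted(a) for a in adj]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.intp)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def mean_aggregation_matrix(self) -> np.ndarray:
        """Row-normalized adjacency: row v averages v's neighbors (zero row if isolated)."""
        a = self.adjacency_matrix()
        deg = a.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(deg > 0, a / deg, 0.0)
        return m


@dataclass(frozen=True)
class DegreeStats:
    min_degree: int
    max_degree: int
    mean_degree: float
    n_isolated: int


# ---------------------------------------------------------------------------
# structure parsing
# ---------------------------------------------------------------------------

def parse_structure(path, chain: Optional[str] = None, model_index: int = 0,
                    alphafold: bool = False) -> ResidueCoordinates:
    """Extract per-residue Cbeta (fallback Calpha) coordinates from a structure file.

    Parameters
    ----------
    path
        PDB file; mmCIF accepted when the extension is ``.cif``/``.mmcif``.
    chain
        Chain id to read; default is the first chain in file order.
    model_index
        Model to use in multi-model (NMR) files.
    alphafold
        Treat the B-factor column as pLDDT and store it.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if path.suffix.lower() in {".cif", ".mmcif"}:
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))

    models = list(structure)
    if not models:
        raise EmptyChainError(f"no models in {path}")
    model = models[min(model_index, len(models) - 1)]

    chains = {c.id: c for c in model}
    if chain is None:
        selected = next(iter(model))
    elif chain in chains:
        selected = chains[chain]
    else:
        raise ChainNotFoundError(
            f"chain {chain!r} not found in {path.name}; available: {sorted(chains)}"
        )

    coords, names, bfactors = [], [], []
    for residue in selected:
        if residue.id[0] != " ":  # skip HETATM / water
            continue
        atom = None
        if "CB" in residue:
            atom = residue["CB"]
        elif "CA" in residue:
            atom = residue["CA"]
        names.append(residue.get_resname())
        if atom is None:
            coords.append([np.nan, np.nan, np.nan])
            bfactors.append(np.nan)
        else:
            # Biopython's disordered atoms already resolve to the
            # highest-occupancy altloc conformer.
            coords.append(atom.get_coord().astype(np.float64))
            bfactors.append(float(atom.get_bfactor()))
    if not coords:
        raise EmptyChainError(f"chain {selected.id!r} of {path.name} has no polymer residues")

    plddt = None
    if alphafold:
        plddt = np.array(bfactors, dtype=np.float64)
        plddt = np.clip(np.nan_to_num(plddt, nan=0.0), 0.0, 100.0)

    rc = ResidueCoordinates(protein_id=path.stem, coords=np.array(coords),
                            residue_names=names, plddt=plddt)
    n_missing = int(rc.missing_mask().sum())
    if n_missing:
        logger.warning("%s: %d residue(s) without coordinates kept as isolated nodes",
                       rc.protein_id, n_missing)
    return rc


# ---------------------------------------------------------------------------
# distances and contacts
# ---------------------------------------------------------------------------

def compute_distance_matrix(rc: ResidueCoordinates) -> np.ndarray:
    """Pairwise Euclidean distances (angstroms); MISSING rows/cols become +inf."""
    coords = rc.coords
    missing = rc.missing_mask()
    filled = np.where(missing[:, None], 0.0, coords)
    dist = squareform(pdist(filled))
    dist[missing, :] = MISSING_DISTANCE
    dist[:, missing] = MISSING_DISTANCE
    np.fill_diagonal(dist, 0.0)
    return dist


def build_contact_graph(dist: np.ndarray, threshold: float = DEFAULT_CONTACT_THRESHOLD,
                        min_seq_sep: int = 1) -> ContactGraph:
    """Threshold a distance matrix into a contact graph.

    An edge {i, j} exists iff |i - j| >= min_seq_sep and dist[i, j] <= threshold;
    the boundary distance (exactly ``threshold``) counts as a contact.
    Residues at infinite distance (missing coordinates) end up isolated.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError(f"distance matrix must be square, got {dist.shape}")
    if not np.array_equal(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=max(1, int(min_seq_sep)))
    hit = dist[iu, ju] <= threshold
    edges = frozenset((int(i), int(j)) for i, j in zip(iu[hit], ju[hit]))
    return ContactGraph(n_nodes=n, edges=edges)


def contact_graph_from_coordinates(rc: ResidueCoordinates,
                                   threshold: float = DEFAULT_CONTACT_THRESHOLD,
                                   min_seq_sep: int = 1) -> ContactGraph:
    """Convenience composition of distance computation and thresholding."""
    return build_contact_graph(compute_distance_matrix(rc), threshold=threshold,
                               min_seq_sep=min_seq_sep)


def graph_degree_stats(g: ContactGraph) -> DegreeStats:
    deg = g.degrees()
    if len(deg) == 0:
        return DegreeStats(0, 0, 0.0, 0)
    return DegreeStats(
        min_degree=int(deg.min()),
        max_degree=int(deg.max()),
        mean_degree=float(deg.mean()),
        n_isolated=int((deg == 0).sum()),
    )


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def write_edge_list(g: ContactGraph, path) -> None:
    """TSV edge list: header with node count, then `i<TAB>j` (0-based, i<j)."""
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={g.n_nodes}\n")
        for i, j in sorted(g.edges):
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path) -> ContactGraph:
    n_nodes = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_nodes=" in line:
                    n_nodes = int(line.split("n_nodes=")[1])
                continue
            i, j = (int(x) for x in line.split("\t"))
            edges.append((min(i, j), max(i, j)))
    if n_nodes is None:
        n_nodes = max((j for _, j in edges), default=-1) + 1
    return ContactGraph(n_nodes=n_nodes, edges=frozenset(edges))
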