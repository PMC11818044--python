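"""Fully offline synthetic corpora: chains, sequences, side files, labels.

The generator emulates the shape of a real phosphosite corpus without any
downloads.  Chains are self-avoiding biased random walks with a 3.8 A
step (the Calpha-Calpha virtual bond length); the ``compaction`` knob
pulls each step toward the running centroid, collapsing the walk into a
globule and creating the long-range contacts that make the 8 A contact
graph non-trivial.  Sequences carry S/T/Y at a controllable fraction.

Ground-truth labels are planted by one of three rules:

``structural``
    an S/T/Y site is positive iff at least two of its contact-graph
    neighbors are positively charged (K, R, H); the signal lives in the
    graph, so only a structure-aware model can fully recover it.
``sequence_only``
    positive iff the +/-3 sequence window contains the motif "RR"; the
    signal is purely local in sequence and ignores the structure.
``random``
    labels are fair coin flips; nothing is learnable.

Labels are then flipped independently with probability ``noise_rate``
(structural and sequence_only modes).  Side files — PSI-BLAST-dialect
PSSMs, SPOT-1D-single-style SS tables, hashstub embeddings — are written
in exactly the dialects the readers in `feature_encoding` and
`plm_projection` parse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .feature_encoding import AMINO_ACIDS, SS_COLUMNS
from .model import SiteSet, sites_from_sequence
from .plm_projection import EmbeddingMatrix, HashStubProvider
from .structure_graph import ContactGraph, ResidueCoordinates, contact_graph_from_coordinates

POSITIVE_CHARGE_CLASS = frozenset("KRH")
SEQUENCE_MOTIF = "RR"
STRUCTURAL_NEIGHBOR_THRESHOLD = 2

#: compaction giving mean contact degree in the 6-10 range typical of real
#: Cbeta maps at 8 A (checked on generated chains of length 80-150)
DEFAULT_COMPACTION = 0.8


@dataclass
class SyntheticSpec:
    """Study conditions for a generated corpus."""

    n_proteins: int = 60
    length_range: tuple = (80, 150)
    step_length: float = 3.8
    compaction: float = DEFAULT_COMPACTION
    sty_fraction: float = 0.15
    signal_mode: str = "structural"
    noise_rate: float = 0.05
    n_families: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < 5:
            raise ValueError("minimum length must be >= 5")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5) for learnable labels")
        if self.signal_mode not in ("structural", "sequence_only", "random"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")


@dataclass
class SyntheticProtein:
    protein_id: str
    sequence: str
    coordinates: ResidueCoordinates
    graph: ContactGraph
    site_set: SiteSet           # all S/T/Y sites with planted labels
    pssm: np.ndarray            # L x 20 integer log-odds
    ss: np.ndarray              # L x 11
    embeddings: np.ndarray      # L x p (hashstub)
    family: str = ""
    plddt_mean: float = 0.0


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    proteins: list

    def __iter__(self):
        return iter(self.proteins)

    def __len__(self):
        return len(self.proteins)


# ---------------------------------------------------------------------------
# chains and sequences
# ---------------------------------------------------------------------------

#: globule radius per cube-root residue: R = _RADIUS_SCALE * L^(1/3) gives
#: ~150 cubic angstroms per residue, matching globular-protein packing
_RADIUS_SCALE = 3.3
#: minimum distance between non-bonded representative atoms
_MIN_SEPARATION = 4.5


def generate_chain(length: int, spec: SyntheticSpec,
                   rng: np.random.Generator,
                   plddt: Optional[np.ndarray] = None,
                   protein_id: str = "synthetic") -> ResidueCoordinates:
    """Self-avoiding confined random walk with exact ``step_length`` steps.

    Steps are uniform random directions inside a globule of radius
    R = 3.3 * L^(1/3) (protein-like packing density); once the walk strays
    outside R, its direction is biased back toward the running centroid
    with weight ``compaction``.  compaction=0 is a free (unconfined) walk;
    higher values collapse the chain and create long-range contacts.
    Non-bonded points are kept at least 4.5 angstroms apart where possible.
    """
    coords = np.zeros((length, 3))
    radius = _RADIUS_SCALE * length ** (1.0 / 3.0)
    for i in range(1, length):
        centroid = coords[:i].mean(axis=0)
        offset = coords[i - 1] - centroid
        outside = np.linalg.norm(offset) > radius
        pull = -offset / max(np.linalg.norm(offset), 1e-9)
        best, best_sep = None, -np.inf
        for _ in range(20):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            if outside and spec.compaction > 0:
                d = (1.0 - spec.compaction) * u + spec.compaction * pull
                dn = np.linalg.norm(d)
                d = d / dn if dn > 1e-9 else u
            else:
                d = u
            candidate = coords[i - 1] + spec.step_length * d
            sep = (np.linalg.norm(coords[:i - 1] - candidate, axis=1).min()
                   if i > 1 else np.inf)
            if sep >= _MIN_SEPARATION:
                best = candidate
                break
            if sep > best_sep:
                best, best_sep = candidate, sep
        coords[i] = best
    return ResidueCoordinates(protein_id=protein_id, coords=coords,
                              residue_names=[], plddt=plddt)


def generate_sequence(length: int, spec: SyntheticSpec,
                      rng: np.random.Generator) -> str:
    """Residue draw with S/T/Y at ``sty_fraction`` total.

    In ``sequence_only`` mode arginine is boosted to 20% so the planted
    "RR" motif has non-degenerate prevalence; otherwise the 17 non-S/T/Y
    residues share the remaining mass uniformly.
    """
    sty = "STY"
    others = [aa for aa in AMINO_ACIDS if aa not in sty]
    probs = {aa: spec.sty_fraction / 3.0 for aa in sty}
    if spec.signal_mode == "sequence_only":
        probs["R"] = 0.20
        rest = 1.0 - spec.sty_fraction - 0.20
        for aa in others:
            if aa != "R":
                probs[aa] = rest / (len(others) - 1)
    else:
        for aa in others:
            probs[aa] = (1.0 - spec.sty_fraction) / len(others)
    alphabet = sorted(probs)
    p = np.array([probs[aa] for aa in alphabet])
    p /= p.sum()
    return "".join(rng.choice(alphabet, size=length, p=p))


# ---------------------------------------------------------------------------
# label planting
# ---------------------------------------------------------------------------

def plant_labels(rc: ResidueCoordinates, sequence: str, graph: ContactGraph,
                 spec: SyntheticSpec, rng: np.random.Generator) -> SiteSet:
    """Ground-truth labels for every S/T/Y site under the spec's signal rule."""
    base = sites_from_sequence(rc.protein_id, sequence)
    if len(base) == 0:
        import warnings
        warnings.warn(f"{rc.protein_id}: no S/T/Y residues, empty site set",
                      stacklevel=2)
        return base
    neighbors = graph.neighbors()
    labels = np.zeros(len(base), dtype=np.intp)
    for row, idx in enumerate(base.site_indices):
        if spec.signal_mode == "structural":
            count = sum(1 for j in neighbors[idx]
                        if sequence[j].upper() in POSITIVE_CHARGE_CLASS)
            labels[row] = int(count >= STRUCTURAL_NEIGHBOR_THRESHOLD)
        elif spec.signal_mode == "sequence_only":
            window = sequence[max(0, idx - 3):idx + 4].upper()
            labels[row] = int(SEQUENCE_MOTIF in window)
        else:  # random
            labels[row] = int(rng.random() < 0.5)
    if spec.signal_mode != "random" and spec.noise_rate > 0:
        flips = rng.random(len(labels)) < spec.noise_rate
        labels = np.where(flips, 1 - labels, labels)
    return SiteSet(protein_id=base.protein_id, site_indices=base.site_indices,
                   labels=labels)


# ---------------------------------------------------------------------------
# side files
# ---------------------------------------------------------------------------

def make_pssm(sequence: str, rng: np.random.Generator) -> np.ndarray:
    """Integer log-odds peaked (+5) on the true residue with small noise."""
    L = len(sequence)
    matrix = rng.integers(-2, 3, size=(L, 20))
    for i, aa in enumerate(sequence.upper()):
        col = AMINO_ACIDS.find(aa)
        if col >= 0:
            matrix[i, col] = 5
    return matrix.astype(np.int64)


def write_pssm(sequence: str, matrix: np.ndarray, path) -> None:
    """Serialize in the PSI-BLAST `-out_ascii_pssm` dialect."""
    header = " ".join(AMINO_ACIDS)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted, "
                 "observed percentages rounded down\n")
        fh.write(f"            {header}   {header}\n")
        for i, aa in enumerate(sequence.upper()):
            scores = " ".join(f"{int(v):3d}" for v in matrix[i])
            pct = " ".join(f"{0:3d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {aa} {scores}  {pct}  0.00 0.00\n")
        fh.write("\n")


def make_ss(length: int, rng: np.random.Generator) -> np.ndarray:
    """SS-class probabilities (Dirichlet rows summing to 1) + ASA/HSE columns."""
    classes = rng.dirichlet(np.full(8, 0.5), size=length)
    asa = rng.uniform(0.0, 200.0, size=(length, 1))
    hseu = rng.integers(0, 40, size=(length, 1)).astype(np.float64)
    hsed = rng.integers(0, 40, size=(length, 1)).astype(np.float64)
    return np.hstack([classes, asa, hseu, hsed])


def write_ss(table: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SS_COLUMNS) + "\n")
        for row in table:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def write_pdb(rc: ResidueCoordinates, sequence: str, path,
              plddt: Optional[np.ndarray] = None) -> None:
    """Single-chain PDB with one representative atom per residue.

    Glycine gets a CA atom, everything else a CB atom, so the parser's
    Cbeta-with-Calpha-fallback rule is exercised on read-back.  The
    B-factor column stores pLDDT when provided.
    """
    three = _THREE_LETTER
    with open(path, "w") as fh:
        serial = 1
        for i, (aa, xyz) in enumerate(zip(sequence.upper(), rc.coords)):
            if np.isnan(xyz).any():
                continue
            name = "CA" if aa == "G" else "CB"
            bfac = float(plddt[i]) if plddt is not None else 0.0
            fh.write(
                f"ATOM  {serial:5d}  {name:<3s}{three.get(aa, 'UNK'):>4s} A"
                f"{i + 1:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{bfac:6.2f}           C\n")
            serial += 1
        fh.write("END\n")


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def generate_protein(spec: SyntheticSpec, index: int,
                     embedding_provider: Optional[HashStubProvider] = None) -> SyntheticProtein:
    """Deterministic per-(seed, index) synthesis of one protein."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))
    pid = f"SYN{index:04d}"
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    sequence = generate_sequence(length, spec, rng)
    base_plddt = rng.uniform(50.0, 95.0)
    plddt = np.clip(base_plddt + rng.normal(0.0, 5.0, size=length), 0.0, 100.0)
    rc = generate_chain(length, spec, rng, plddt=plddt, protein_id=pid)
    graph = contact_graph_from_coordinates(rc)
    site_set = plant_labels(rc, sequence, graph, spec, rng)
    pssm = make_pssm(sequence, rng)
    ss = make_ss(length, rng)
    provider = embedding_provider or HashStubProvider(seed=spec.seed)
    emb = provider(sequence)
    family = f"FAM{int(rng.integers(spec.n_families)):03d}"
    return SyntheticProtein(protein_id=pid, sequence=sequence, coordinates=rc,
                            graph=graph, site_set=site_set, pssm=pssm, ss=ss,
                            embeddings=emb, family=family,
                            plddt_mean=float(plddt.mean()))


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    provider = HashStubProvider(seed=spec.seed)
    proteins = [generate_protein(spec, i, embedding_provider=provider)
                for i in range(spec.n_proteins)]
    return SyntheticCorpus(spec=spec, proteins=proteins)


def write_corpus(corpus: SyntheticCorpus, out_dir) -> Path:
    """Emit FASTA, PDBs, PSSMs, SS tables, embeddings, annotations, manifest."""
    from .plm_projection import save_embeddings

    out = Path(out_dir)
    for sub in ("pdb", "pssm", "ss"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    with open(out / "sequences.fasta", "w") as fh:
        for p in corpus:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")

    embeddings = []
    manifest_rows = []
    annotation_rows = []
    for p in corpus:
        write_pdb(p.coordinates, p.sequence, out / "pdb" / f"{p.protein_id}.pdb",
                  plddt=p.coordinates.plddt)
        write_pssm(p.sequence, p.pssm, out / "pssm" / f"{p.protein_id}.pssm")
        write_ss(p.ss, out / "ss" / f"{p.protein_id}.tsv")
        embeddings.append(EmbeddingMatrix(protein_id=p.protein_id,
                                          values=p.embeddings,
                                          provider_tag="hashstub"))
        manifest_rows.append(
            (p.protein_id, "sequences.fasta", f"pdb/{p.protein_id}.pdb",
             f"pssm/{p.protein_id}.pssm", f"ss/{p.protein_id}.tsv", p.family))
        for idx, label in zip(p.site_set.site_indices, p.site_set.labels):
            if label == 1:
                annotation_rows.append(
                    (p.protein_id, int(idx) + 1, p.sequence[idx], 1))

    save_embeddings(out / "embeddings.h5", embeddings)

    with open(out / "manifest.tsv", "w") as fh:
        fh.write("protein_id\tsequence_path\tstructure_path\tpssm_path\tss_path\tfamily\n")
        for row in manifest_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("protein_id\tposition\tresidue\tlabel\n")
        for row in annotation_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(out / "spec.json", "w") as fh:
        json.dump(asdict(corpus.spec), fh, indent=2)
    return out
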