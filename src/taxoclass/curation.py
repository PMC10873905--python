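"""Nonredundant, species-specific reference curation.

Builds species-specific sets of nonredundant coding sequences from assembly
metadata and sequence data. The pipeline per species:

1. prioritize assemblies by completeness, annotation category and N50,
   dropping redundant strains down to a per-species cap;
2. estimate all-vs-all average nucleotide identity (ANI) with an
   alignment-free fragment-containment estimator;
3. group assemblies by ANI with OPTICS density clustering;
4. keep the highest-N50 representative per group;
5. collapse coding sequences sharing >= 99% identity.

Redundant near-identical assemblies are what push k-mer LCA classifiers
toward uninformative high-rank calls, so removing them before index or
model construction is the point of this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import OPTICS
from sklearn.metrics import silhouette_samples

from ._kmers import canonical_set
from .errors import (
    AlignmentError,
    DegenerateSequenceError,
    EmptyInputError,
    MixedSpeciesError,
    ShapeError,
    SingleClusterError,
)

ASSEMBLY_LEVELS = ("complete_genome", "chromosome", "scaffold", "contig")
REFSEQ_CATEGORIES = ("reference_genome", "representative_genome", "na")

_LEVEL_PRIORITY = {v: i for i, v in enumerate(ASSEMBLY_LEVELS)}
_CATEGORY_PRIORITY = {v: i for i, v in enumerate(REFSEQ_CATEGORIES)}


@dataclass
class AssemblyRecord:
    """One assembly-metadata row, optionally carrying its coding sequences."""

    accession: str
    species: int
    assembly_level: str
    refseq_category: str = "na"
    strain: str = ""
    n50: int = 1
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.assembly_level not in _LEVEL_PRIORITY:
            raise ValueError(f"unknown assembly_level {self.assembly_level!r}")
        if self.refseq_category not in _CATEGORY_PRIORITY:
            raise ValueError(f"unknown refseq_category {self.refseq_category!r}")
        if self.n50 < 1:
            raise ValueError("n50 must be >= 1")


@dataclass
class AniMatrix:
    accessions: list[str]
    values: np.ndarray  # symmetric, percent in [0, 100], diagonal 100

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError("ANI matrix must be square")
        if v.shape[0] != len(self.accessions):
            raise ShapeError("accession list does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ShapeError("ANI matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ShapeError("ANI diagonal must be exactly 100")
        self.values = v

    def to_distances(self) -> np.ndarray:
        """Dissimilarity fed to clustering: (100 - ANI) / 100."""
        d = (100.0 - self.values) / 100.0
        np.fill_diagonal(d, 0.0)
        return d


@dataclass(frozen=True)
class ClusterParams:
    """OPTICS parameters; defaults follow the tuned curation setting
    (min_samples=2, everything else at the algorithm's defaults)."""

    min_samples: int = 2
    max_eps: float = math.inf
    xi: float = 0.05

    def __post_init__(self) -> None:
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")
        if not 0.0 < self.xi < 1.0:
            raise ValueError("xi must be in (0, 1)")


@dataclass(frozen=True)
class CurationConfig:
    per_species_cap: int = 10
    dedup_identity: float = 0.99
    ani_kmer: int = 16
    ani_fragment_len: int = 3000
    dedup_kmer: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.dedup_identity <= 1.0:
            raise ValueError("dedup_identity must be in (0, 1]")
        if self.per_species_cap < 1:
            raise ValueError("per_species_cap must be >= 1")


# -- assembly prioritization --------------------------------------------------

def _priority_key(r: AssemblyRecord) -> tuple:
    return (
        _LEVEL_PRIORITY[r.assembly_level],
        _CATEGORY_PRIORITY[r.refseq_category],
        -r.n50,
        r.accession,
    )


def prioritize_assemblies(
    records: Sequence[AssemblyRecord], cap: int = 10
) -> list[AssemblyRecord]:
    """Rank assemblies and trim the list to at most ``cap`` per species.

    Ordering: assembly completeness (complete genome > chromosome >
    scaffold > contig), then annotation category (reference > representative
    > NA), then N50 descending, with accession as the deterministic
    tie-break. When more than ``cap`` assemblies exist, the worst-ranked
    assemblies whose strain is already represented by a better-ranked one
    are dropped first; only if no such redundant strain remains is the list
    truncated at ``cap``.
    """
    records = list(records)
    if not records:
        return []
    if len({r.species for r in records}) > 1:
        raise MixedSpeciesError(
            f"records span species {sorted({r.species for r in records})}"
        )
    ranked = sorted(records, key=_priority_key)
    if len(ranked) <= cap:
        return ranked
    while len(ranked) > cap:
        drop_idx = None
        for i in range(len(ranked) - 1, -1, -1):
            strain = ranked[i].strain
            if strain and any(r.strain == strain for r in ranked[:i]):
                drop_idx = i
                break
        if drop_idx is None:
            return ranked[:cap]
        del ranked[drop_idx]
    return ranked


# -- ANI estimation -----------------------------------------------------------

def _fragments(seqs: Iterable[str], fragment_len: int, k: int) -> list[str]:
    frags: list[str] = []
    for seq in seqs:
        for i in range(0, len(seq), fragment_len):
            frag = seq[i : i + fragment_len]
            if len(frag) >= k:
                frags.append(frag)
    return frags


def _directional_ani(
    frags: list[str], target_kmers: set[str], k: int, min_containment: float
) -> float:
    identities = []
    for frag in frags:
        kmers = canonical_set(frag, k)
        if not kmers:
            continue
        c = len(kmers & target_kmers) / len(kmers)
        if c >= min_containment:
            identities.append(100.0 * c ** (1.0 / k))
    return float(np.mean(identities)) if identities else 0.0


def estimate_ani(
    seq_set_a: Sequence[str],
    seq_set_b: Sequence[str],
    k: int = 16,
    fragment_len: int = 3000,
    min_containment: float = 0.1,
) -> float:
    """Alignment-free ANI estimate between two sequence sets, in percent.

    Each set is cut into ``fragment_len`` fragments; a fragment's identity
    against the other set is ``100 * c**(1/k)`` where ``c`` is the canonical
    k-mer containment of the fragment in the other set — the expected
    k-mer survival under divergence ``d`` is ``(1-d)**k``, so ``c**(1/k)``
    inverts the survival curve back to per-base identity. Fragments below
    containment ``min_containment`` are treated as non-homologous and
    excluded, mirroring the fragment-filtering of mapping-based ANI tools.
    The reported value is the mean of both directions; 0 when no fragment
    passes in either direction.
    """
    if not seq_set_a or not seq_set_b:
        raise EmptyInputError("both sequence sets must be non-empty")
    if fragment_len <= k:
        raise ValueError("fragment_len must exceed k")
    frags_a = _fragments(seq_set_a, fragment_len, k)
    frags_b = _fragments(seq_set_b, fragment_len, k)
    if not frags_a or not frags_b:
        raise DegenerateSequenceError(
            f"all fragments shorter than k={k}"
        )
    kmers_a: set[str] = set()
    for s in seq_set_a:
        kmers_a |= canonical_set(s, k)
    kmers_b: set[str] = set()
    for s in seq_set_b:
        kmers_b |= canonical_set(s, k)
    ab = _directional_ani(frags_a, kmers_b, k, min_containment)
    ba = _directional_ani(frags_b, kmers_a, k, min_containment)
    return (ab + ba) / 2.0


def ani_matrix(
    assemblies: Sequence[AssemblyRecord], cfg: CurationConfig = CurationConfig()
) -> AniMatrix:
    """All-vs-all ANI among assemblies of one species."""
    if not assemblies:
        raise EmptyInputError("no assemblies")
    n = len(assemblies)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                v = estimate_ani(
                    assemblies[i].sequences,
                    assemblies[j].sequences,
                    k=cfg.ani_kmer,
                    fragment_len=cfg.ani_fragment_len,
                )
            except (EmptyInputError, DegenerateSequenceError) as err:
                raise type(err)(
                    f"{assemblies[i].accession} vs "
                    f"{assemblies[j].accession}: {err}"
                ) from err
            m[i, j] = m[j, i] = v
    return AniMatrix([a.accession for a in assemblies], m)


# -- density clustering -------------------------------------------------------

def optics_cluster(
    distances: np.ndarray, params: ClusterParams = ClusterParams()
) -> np.ndarray:
    """OPTICS labels over a precomputed dissimilarity matrix.

    Reachability ordering with core distances at ``min_samples`` followed by
    xi-steepness cluster extraction; points never reached within ``max_eps``
    are noise (-1). Deterministic given the input order. Labels are
    renumbered by first appearance so equal inputs give equal outputs.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ShapeError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ShapeError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ShapeError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ShapeError("distance diagonal must be zero")
    n = d.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    if n < params.min_samples:
        return np.full(n, -1, dtype=int)
    with warnings.catch_warnings():
        # all-noise inputs legitimately produce all-inf reachability
        warnings.simplefilter("ignore", UserWarning)
        model = OPTICS(
            min_samples=params.min_samples,
            max_eps=params.max_eps,
            xi=params.xi,
            cluster_method="xi",
            metric="precomputed",
        ).fit(d)
    labels = model.labels_
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab == -1:
            out[i] = -1
        else:
            if lab not in remap:
                remap[lab] = len(remap)
            out[i] = remap[lab]
    return out


def mean_silhouette(distances: np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette coefficient over non-noise points.

    Points in singleton clusters contribute 0 by convention; if every
    cluster is a singleton the mean is 0. Fewer than two clusters after
    noise removal is an error.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    if d.shape[0] != len(labels):
        raise AlignmentError("labels do not match distance matrix")
    keep = labels != -1
    if keep.sum() == 0:
        raise SingleClusterError("no clustered points")
    d = d[np.ix_(keep, keep)]
    labs = labels[keep]
    uniq, counts = np.unique(labs, return_counts=True)
    if len(uniq) < 2:
        raise SingleClusterError("silhouette needs >= 2 clusters")
    if (counts == 1).all():
        return 0.0
    vals = silhouette_samples(d, labs, metric="precomputed")
    return float(np.mean(vals))


def select_representatives(
    labels: Sequence[int], records: Sequence[AssemblyRecord]
) -> list[AssemblyRecord]:
    """One representative per cluster: the highest-N50 member, accession as
    tie-break. Noise points are promoted to singleton clusters and kept."""
    if len(labels) != len(records):
        raise AlignmentError(
            f"{len(labels)} labels for {len(records)} records"
        )
    groups: dict[object, list[AssemblyRecord]] = {}
    order: list[object] = []
    for i, (lab, rec) in enumerate(zip(labels, records)):
        key = ("noise", i) if lab == -1 else ("cluster", int(lab))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    out = []
    for key in order:
        out.append(min(groups[key], key=lambda r: (-r.n50, r.accession)))
    return out


# -- sequence-level deduplication --------------------------------------------

def _dedupe_indices(
    seqs: Sequence[str], identity: float, k: int
) -> list[int]:
    """Indices of greedy longest-first cluster representatives."""
    if not seqs:
        raise EmptyInputError("no sequences to deduplicate")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
    reps: list[tuple[int, set[str]]] = []  # (orig index, canonical k-mers)
    for idx in order:
        kmers = canonical_set(seqs[idx], k)
        joined = False
        if kmers:
            for _, rep_kmers in reps:
                c = len(kmers & rep_kmers) / len(kmers)
                if c ** (1.0 / k) >= identity:
                    joined = True
                    break
        if not joined:
            reps.append((idx, kmers))
    return sorted(idx for idx, _ in reps)


def dedupe_sequences(
    seqs: Sequence[str], identity: float = 0.99, k: int = 10
) -> list[str]:
    """Collapse sequences sharing ``identity`` (default 99%) into one
    representative each.

    Greedy longest-first clustering: a sequence joins the first existing
    representative whose estimated identity — canonical k-mer containment of
    the shorter in the longer, mapped through ``c**(1/k)`` — meets the
    threshold, else it founds a new cluster. Representatives are returned in
    input order. Both strands are compared via canonical k-mers, so
    reverse-complement duplicates collapse.
    """
    return [seqs[i] for i in _dedupe_indices(seqs, identity, k)]


# -- end-to-end per-species curation -----------------------------------------

def curate_species(
    records: Sequence[AssemblyRecord],
    cfg: CurationConfig = CurationConfig(),
    params: ClusterParams = ClusterParams(),
) -> dict[int, list[str]]:
    """Run the full curation pipeline per species.

    Returns a map species taxid -> nonredundant coding-sequence list. Every
    stage is deterministic, and species are processed independently.
    """
    by_species: dict[int, list[AssemblyRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    out: dict[int, list[str]] = {}
    for species in sorted(by_species):
        recs = prioritize_assemblies(by_species[species], cfg.per_species_cap)
        try:
            am = ani_matrix(recs, cfg)
            labels = optics_cluster(am.to_distances(), params)
            reps = select_representatives(labels, recs)
            pooled: list[str] = []
            for rep in reps:
                pooled.extend(rep.sequences)
            out[species] = dedupe_sequences(
                pooled, cfg.dedup_identity, cfg.dedup_kmer
            )
        except Exception as err:
            raise type(err)(f"species {species}: {err}") from err
    return out


# -- external interfaces ------------------------------------------------------

def _normalize_vocab(value: str) -> str:
    return value.strip().lower().replace(" ", "_")


_METADATA_COLUMNS = [
    "accession",
    "species_taxid",
    "assembly_level",
    "refseq_category",
    "strain",
    "n50",
    "fasta_path",
]


def read_assembly_metadata(path, load_sequences: bool = True) -> list[AssemblyRecord]:
    """Read the assembly-metadata TSV dialect.

    Header columns: accession, species_taxid, assembly_level,
    refseq_category, strain, n50, fasta_path. Vocabulary values are
    normalized case-insensitively ("Complete Genome" -> complete_genome).
    FASTA paths resolve relative to the table's directory.
    """
    from Bio import SeqIO

    path = Path(path)
    records: list[AssemblyRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _METADATA_COLUMNS:
            raise ValueError(
                f"{path}: expected header {_METADATA_COLUMNS}, got {header}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            acc, taxid, level, cat, strain, n50, fasta = line.split("\t")
            rec = AssemblyRecord(
                accession=acc,
                species=int(taxid),
                assembly_level=_normalize_vocab(level),
                refseq_category=_normalize_vocab(cat) or "na",
                strain=strain,
                n50=int(n50),
            )
            if load_sequences and fasta:
                fasta_path = path.parent / fasta
                rec.sequences = [
                    str(r.seq).upper() for r in SeqIO.parse(fasta_path, "fasta")
                ]
            records.append(rec)
    return records


def write_species_fasta(
    curated: dict[int, list[str]], outdir, accession: str = "curated"
) -> list[Path]:
    """Write one ``<taxid>.fna`` multi-FASTA per species.

    Headers follow the ``<accession>|<seq_id>`` convention.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for species in sorted(curated):
        p = outdir / f"{species}.fna"
        with open(p, "w") as fh:
            for i, seq in enumerate(curated[species]):
                fh.write(f">{accession}|cds{i}\n{seq}\n")
        paths.append(p)
    return paths
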