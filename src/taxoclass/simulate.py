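"""Synthetic bacterial communities for end-to-end, download-free testing.

The generator produces:

* a complete balanced taxonomy of configurable shape;
* hierarchically diverged genomes — one random ancestor per phylum, with
  i.i.d. substitutions applied on every branch at a per-rank divergence
  that shrinks from phylum to species, so sister species are more similar
  than cross-genus pairs by construction;
* disjoint train/test assembly panels per species (further strain-level
  substitution; test accessions never enter any index or model, which is
  what makes downstream evaluation leakage-free);
* error-bearing 150 bp paired-end reads with Gaussian insert sizes and a
  uniform per-base substitution error model.

Substitution-only evolution (no indels) keeps ANI and identity
expectations closed-form: after a branch of divergence d, a k-mer survives
with probability (1-d)^k and pairwise ANI between two taxa split by
branches d1, d2 is about 100*(1 - d1 - d2).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from ._kmers import revcomp
from .curation import AssemblyRecord
from .errors import (
    ConfigError,
    EmptySpeciesError,
    ShapeError,
    ShortSequenceError,
)
from .taxonomy import SUB_ROOT_RANKS, Taxonomy, build_taxonomy

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class TaxonomyShape(NamedTuple):
    """Children counts per rank: e.g. (2, 1, 1, 1, 2, 3) means 2 phyla,
    1 class per phylum, ..., 2 genera per family, 3 species per genus."""

    phyla: int
    classes: int
    orders: int
    families: int
    genera: int
    species: int


#: Per-branch substitution fractions, shrinking toward the leaves.
DEFAULT_DIVERGENCE: dict[str, float] = {
    "phylum": 0.25,
    "class": 0.15,
    "order": 0.10,
    "family": 0.06,
    "genus": 0.04,
    "species": 0.015,
}


@dataclass(frozen=True)
class SimulationConfig:
    shape: TaxonomyShape = TaxonomyShape(2, 1, 1, 1, 2, 3)
    genome_len: int = 20_000
    divergence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERGENCE)
    )
    n_assemblies_per_species: int = 3
    n_test_assemblies: int = 1
    strain_divergence: float = 0.002
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    error_rate: float = 0.005
    reads_per_species: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.shape):
            raise ShapeError(f"all shape counts must be >= 1: {self.shape}")
        div = [self.divergence[r] for r in SUB_ROOT_RANKS]
        if any(not 0.0 <= d < 1.0 for d in div):
            raise ConfigError("divergences must be fractions in [0, 1)")
        if any(a <= b for a, b in zip(div, div[1:])):
            raise ConfigError(
                "per-rank divergence must strictly decrease from phylum "
                "to species"
            )
        if not 0.0 <= self.strain_divergence < 1.0:
            raise ConfigError("strain_divergence must be in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.genome_len < self.read_len:
            raise ConfigError("genome_len must be >= read_len")


@dataclass
class SyntheticCommunity:
    taxonomy: Taxonomy
    train_assemblies: dict[int, list[AssemblyRecord]]
    test_assemblies: dict[int, list[AssemblyRecord]]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage random stream derived from one global seed by
    stable hashing of the stage name."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(stage.encode())]
    )


# ----------------------------- taxonomy ------------------------------------

def synth_taxonomy(shape: TaxonomyShape, seed: int = 0) -> Taxonomy:
    """Complete balanced taxonomy with deterministic sequential taxids."""
    shape = TaxonomyShape(*shape)
    if any(c < 1 for c in shape):
        raise ShapeError(f"all shape counts must be >= 1: {shape}")
    records = [(1, 1, "root", "root")]
    next_id = 2
    frontier = [1]
    for rank, count in zip(SUB_ROOT_RANKS, shape):
        new_frontier = []
        for parent in frontier:
            for i in range(count):
                taxid = next_id
                next_id += 1
                records.append(
                    (taxid, parent, rank, f"{rank[:1].upper()}{taxid}")
                )
                new_frontier.append(taxid)
        frontier = new_frontier
    return build_taxonomy(records)


# ------------------------------ genomes -------------------------------------

def _mutate(genome: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions at rate d; a hit site always changes base."""
    if d <= 0:
        return genome.copy()
    out = genome.copy()
    hits = np.flatnonzero(rng.random(genome.size) < d)
    out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _to_str(genome: np.ndarray) -> str:
    return _BASES[genome].tobytes().decode()


def _segment_bounds(
    n: int, rng: np.random.Generator, lo: int = 300, hi: int = 3000
) -> list[tuple[int, int]]:
    """Partition [0, n) into CDS-like segments of uniform 300-3000 bp."""
    bounds = []
    pos = 0
    while pos < n:
        seg = int(rng.integers(lo, hi + 1))
        end = min(pos + seg, n)
        if n - end < lo:  # fold a short remainder into the last segment
            end = n
        bounds.append((pos, end))
        pos = end
    return bounds


def evolve_genomes(t: Taxonomy, cfg: SimulationConfig) -> SyntheticCommunity:
    """Evolve genomes down the taxonomy and package them as assemblies.

    One random ancestral genome per phylum; every branch below applies
    i.i.d. substitutions at its rank's divergence. Each species then gets
    ``n_assemblies_per_species`` train assemblies and ``n_test_assemblies``
    test assemblies by further strain-level substitution, with disjoint
    accession namespaces. Genomes are cut into CDS-like segments at
    species-level boundaries shared by all of a species' assemblies.
    """
    rng = stage_rng(cfg.seed, "evolve")
    genomes: dict[int, np.ndarray] = {}
    for phylum in t.taxa_at_rank("phylum"):
        genomes[phylum] = rng.integers(
            0, 4, size=cfg.genome_len, dtype=np.uint8
        )
    for rank in SUB_ROOT_RANKS[1:]:
        d = cfg.divergence[rank]
        for taxid in t.taxa_at_rank(rank):
            genomes[taxid] = _mutate(genomes[t.parent_of(taxid)], d, rng)

    train: dict[int, list[AssemblyRecord]] = {}
    test: dict[int, list[AssemblyRecord]] = {}
    levels = ("complete_genome", "chromosome", "scaffold", "contig")
    for sp in t.taxa_at_rank("species"):
        bounds = _segment_bounds(cfg.genome_len, rng)

        def make(prefix: str, i: int, category: str) -> AssemblyRecord:
            strain_genome = _mutate(genomes[sp], cfg.strain_divergence, rng)
            return AssemblyRecord(
                accession=f"{prefix}{sp}.{i:02d}",
                species=sp,
                assembly_level=levels[min(i, len(levels) - 1)],
                refseq_category=category,
                strain=f"strain-{sp}-{prefix}{i}",
                n50=int(rng.integers(100_000, 2_000_000)),
                sequences=[
                    _to_str(strain_genome[a:b]) for a, b in bounds
                ],
            )

        train[sp] = [
            make("A", i, "representative_genome" if i == 0 else "na")
            for i in range(cfg.n_assemblies_per_species)
        ]
        test[sp] = [
            make("T", i, "na") for i in range(cfg.n_test_assemblies)
        ]
    return SyntheticCommunity(taxonomy=t, train_assemblies=train,
                              test_assemblies=test)


def simulate_community(cfg: SimulationConfig) -> SyntheticCommunity:
    """Convenience: taxonomy plus evolved genomes in one call."""
    return evolve_genomes(synth_taxonomy(cfg.shape, cfg.seed), cfg)


# -------------------------------- reads -------------------------------------

def simulate_reads(
    assemblies: Mapping[int, Sequence[AssemblyRecord]],
    cfg: SimulationConfig,
    stage: str = "reads",
) -> list[tuple[tuple[str, str], int]]:
    """Paired-end reads with substitution errors from per-species assemblies.

    Fragments are drawn uniformly across a species' sequences (weighted by
    eligible length) with truncated-Gaussian insert sizes; mate 1 is the
    leading ``read_len`` bases, mate 2 the reverse complement of the
    trailing ``read_len`` bases; each base is substituted i.i.d. at
    ``error_rate``. Deterministic given the config seed; the error
    process draws from its own random stream, so the fragment coordinates
    for a given seed are identical at every error rate.
    """
    rng = stage_rng(cfg.seed, stage)
    err_rng = stage_rng(cfg.seed, stage + ":errors")
    L = cfg.read_len
    out: list[tuple[tuple[str, str], int]] = []
    for sp in sorted(assemblies):
        seqs = [s for rec in assemblies[sp] for s in rec.sequences
                if len(s) >= L]
        if not seqs:
            raise ShortSequenceError(
                f"species {sp}: no sequence reaches read_len={L}"
            )
        weights = np.array([len(s) - L + 1 for s in seqs], dtype=float)
        weights /= weights.sum()
        for _ in range(cfg.reads_per_species):
            si = int(rng.choice(len(seqs), p=weights))
            seq = seqs[si]
            insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            insert = max(L, min(insert, len(seq)))
            start = int(rng.integers(0, len(seq) - insert + 1))
            frag = seq[start : start + insert]
            r1 = _with_errors(frag[:L], cfg.error_rate, err_rng)
            r2 = _with_errors(revcomp(frag[-L:]), cfg.error_rate, err_rng)
            out.append(((r1, r2), sp))
    return out


def _with_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    # map ASCII -> 0..3, mutate, map back
    codes = np.zeros(arr.size, dtype=np.uint8)
    codes[arr == ord("C")] = 1
    codes[arr == ord("G")] = 2
    codes[arr == ord("T")] = 3
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    codes[hits] = (codes[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return _BASES[codes].tobytes().decode()


def label_reads(
    sim_reads: Sequence[tuple[tuple[str, str], int]], prefix: str = "read"
) -> tuple[list[tuple[str, tuple[str, str]]], dict[str, int]]:
    """Attach stable read ids and return (id, pair) tuples plus a truth map.

    Read names follow the ``<prefix><n>|taxid=<species>`` convention so
    truth survives a round-trip through FASTQ.
    """
    labelled = []
    truth = {}
    for i, (pair, sp) in enumerate(sim_reads):
        rid = f"{prefix}{i}|taxid={sp}"
        labelled.append((rid, pair))
        truth[rid] = sp
    return labelled, truth


def balance_training(
    reads_per_species: Mapping[int, Sequence[object]],
    n_per_species: int,
    seed: int = 0,
) -> dict[int, list[object]]:
    """Uniform down-sample (without replacement) to at most
    ``n_per_species`` reads per species; deterministic given the seed."""
    rng = stage_rng(seed, "balance")
    out: dict[int, list[object]] = {}
    for sp in sorted(reads_per_species):
        reads = list(reads_per_species[sp])
        if not reads:
            raise EmptySpeciesError(f"species {sp} has no reads")
        if len(reads) > n_per_species:
            idx = sorted(
                rng.choice(len(reads), size=n_per_species, replace=False)
            )
            reads = [reads[i] for i in idx]
        out[sp] = reads
    return out


# ------------------------------ file output ---------------------------------

def write_paired_fastq(
    labelled: Sequence[tuple[str, tuple[str, str]]], r1_path, r2_path
) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, (r1, r2) in labelled:
            q1 = "I" * len(r1)
            f1.write(f"@{rid}/1\n{r1}\n+\n{q1}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def write_truth_tsv(truth: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tspecies_taxid\n")
        for rid in truth:
            fh.write(f"{rid}\t{truth[rid]}\n")


def write_assembly_metadata(
    community: SyntheticCommunity, outdir, which: str = "train"
) -> None:
    """Write assemblies as per-assembly FASTA plus the metadata TSV dialect
    the curation module reads."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = (community.train_assemblies if which == "train"
             else community.test_assemblies)
    with open(outdir / f"{which}_assemblies.tsv", "w") as fh:
        fh.write("accession\tspecies_taxid\tassembly_level\trefseq_category"
                 "\tstrain\tn50\tfasta_path\n")
        for sp in sorted(table):
            for rec in table[sp]:
                fasta = f"{rec.accession}.fna"
                with open(outdir / fasta, "w") as fa:
                    for i, seq in enumerate(rec.sequences):
                        fa.write(f">{rec.accession}|cds{i}\n{seq}\n")
                fh.write(
                    f"{rec.accession}\t{rec.species}\t{rec.assembly_level}"
                    f"\t{rec.refseq_category}\t{rec.strain}\t{rec.n50}"
                    f"\t{fasta}\n"
                )
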