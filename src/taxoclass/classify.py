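"""Flat read classifiers and prediction-file interoperability.

Three built-in classifiers cover the roles the ensemble layer needs:

* :class:`KmerLcaIndex` — a canonical k-mer -> LCA-taxid map with
  max-scoring-path read classification, the classic reference-based
  k-mer LCA scheme;
* :class:`KmerProfileModel` — a smoothed multinomial (naive-Bayes) profile
  over 13-mer tokens emitting softmax-normalized posteriors, the role a
  trained embedding classifier plays in production pipelines;
* :class:`AlignIndex` — a seed-and-extend ungapped best-hit aligner used
  for per-genus species refinement.

Predictions from external tools (Kraken2/Kaiju tabular output, SAM) can be
imported through :func:`parse_predictions` and ensembled identically.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import softmax as _softmax

from ._kmers import canonical_multiset, canonical_set, revcomp
from .errors import (
    AlphabetError,
    EmptyAllowedError,
    EmptyInputError,
    FormatError,
    SingleLabelError,
    UnknownTaxonError,
)
from .taxonomy import Taxonomy

ReadPair = tuple[str, str | None]

_READ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class Prediction:
    """Per-read taxon assignment. ``taxon is None`` means unclassified, in
    which case ``rank`` and ``confidence`` are None too."""

    read_id: str
    taxon: int | None
    rank: str | None
    confidence: float | None
    source: str

    def __post_init__(self) -> None:
        if (self.taxon is None) != (self.rank is None):
            raise ValueError("taxon and rank must be None together")

    @property
    def is_unclassified(self) -> bool:
        return self.taxon is None

    @classmethod
    def unclassified(cls, read_id: str, source: str) -> "Prediction":
        return cls(read_id, None, None, None, source)


def _check_read(seq: str) -> str:
    seq = seq.upper()
    if not _READ_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _READ_ALPHABET)
        raise AlphabetError(f"read contains non-ACGTN characters {bad}")
    return seq


def _pair_tokens(read_pair: ReadPair, k: int) -> tuple[list[str], int]:
    """Canonical k-mers of both mates (per occurrence) and the count of
    valid windows queried."""
    tokens: list[str] = []
    for mate in read_pair:
        if mate is None:
            continue
        tokens.extend(canonical_multiset(_check_read(mate), k))
    return tokens, len(tokens)


# =========================== k-mer LCA index ================================

class KmerLcaIndex:
    """Canonical k-mer -> LCA-taxid map over a taxonomy.

    Each k-mer maps to the lowest common ancestor of every species whose
    reference sequences contain it. ``lca_storage=False`` is an ablation
    switch that instead stores an arbitrary (first-seen, deterministic)
    containing species, used to quantify how much the LCA convention
    protects against false species calls on unseen taxa.
    """

    def __init__(self, k: int, taxonomy: Taxonomy, lca_storage: bool = True):
        if k < 3:
            raise ValueError("k must be >= 3")
        self.k = k
        self.taxonomy = taxonomy
        self.lca_storage = lca_storage
        self.table: dict[str, int] = {}
        self._species_cache: dict[int, tuple[int, ...]] = {}

    def add_species(self, species: int, sequences: Iterable[str]) -> None:
        t = self.taxonomy
        t._check(species)
        for seq in sequences:
            for kmer in canonical_set(seq, self.k):
                cur = self.table.get(kmer)
                if cur is None:
                    self.table[kmer] = species
                elif self.lca_storage and cur != species:
                    self.table[kmer] = t.lca((cur, species))

    def __len__(self) -> int:
        return len(self.table)

    def _species_below(self, taxid: int) -> tuple[int, ...]:
        cached = self._species_cache.get(taxid)
        if cached is None:
            t = self.taxonomy
            if t.rank_of(taxid) == "species":
                cached = (taxid,)
            else:
                cached = tuple(sorted(t.children_at(taxid, "species")))
            self._species_cache[taxid] = cached
        return cached


def build_lca_index(
    species_sets: Mapping[int, Sequence[str]],
    t: Taxonomy,
    k: int = 21,
    lca_storage: bool = True,
) -> KmerLcaIndex:
    """Build a :class:`KmerLcaIndex` from per-species sequence sets.

    Species are inserted in sorted-taxid order so the index is a pure
    function of its inputs.
    """
    for species in species_sets:
        if species not in t:
            raise UnknownTaxonError(f"species {species} not in taxonomy")
    index = KmerLcaIndex(k, t, lca_storage=lca_storage)
    for species in sorted(species_sets):
        index.add_species(species, species_sets[species])
    return index


def classify_lca(
    index: KmerLcaIndex,
    read_pair: ReadPair,
    conf_threshold: float = 0.0,
    read_id: str = "",
) -> Prediction:
    """Classify a read pair by max-scoring root-to-leaf path.

    Every canonical k-mer of both mates is looked up; hit counts accumulate
    on taxonomy nodes. Each root-to-leaf path is scored by the sum of hits
    on its nodes, and the read classifies to the deepest *hit* node of the
    max-scoring path (ties across paths resolve to the LCA of their deepest
    hit nodes). Confidence is the fraction of queried k-mers lying on the
    chosen root path; below ``conf_threshold`` (default 0, with 0.1 as the
    stringent alternative) the read is left unclassified.
    """
    tokens, total = _pair_tokens(read_pair, index.k)
    hits: dict[int, int] = {}
    for tok in tokens:
        taxid = index.table.get(tok)
        if taxid is not None:
            hits[taxid] = hits.get(taxid, 0) + 1
    if not hits or total == 0:
        return Prediction.unclassified(read_id, "lca")
    t = index.taxonomy
    # candidate leaves: species at or below any hit node
    candidates: set[int] = set()
    for node in hits:
        candidates.update(index._species_below(node))
    if not candidates:  # only root-level hits in a degenerate taxonomy
        candidates = {min(hits)}
    best_score = -1
    best_deepest: list[int] = []
    for leaf in sorted(candidates):
        path = t.root_path(leaf)
        on_path = [n for n in path if n in hits]
        score = sum(hits[n] for n in on_path)
        if score > best_score:
            best_score = score
            best_deepest = [on_path[-1]]
        elif score == best_score:
            best_deepest.append(on_path[-1])
    chosen = best_deepest[0] if len(best_deepest) == 1 else t.lca(best_deepest)
    path_hits = sum(hits.get(n, 0) for n in t.root_path(chosen))
    confidence = path_hits / total
    if confidence < conf_threshold:
        return Prediction.unclassified(read_id, "lca")
    return Prediction(read_id, chosen, t.rank_of(chosen), confidence, "lca")


# ========================= k-mer profile classifier =========================

@dataclass
class KmerProfileModel:
    """Smoothed multinomial profile over canonical k-mer tokens.

    Per label, token probabilities are additively smoothed over the observed
    training vocabulary; prediction sums per-token log-probabilities and
    softmax-normalizes across the (optionally restricted) label set. Tokens
    never seen in training are skipped at prediction time.
    """

    k: int
    labels: list[int]
    vocab: dict[str, int]
    log_probs: np.ndarray  # shape (n_labels, vocab size)
    smoothing: float = 1.0

    def predict(
        self, read_pair: ReadPair, allowed: Iterable[int] | None = None
    ):
        return predict_profile(self, read_pair, allowed)

    @classmethod
    def single_label(cls, label: int, k: int = 13) -> "KmerProfileModel":
        """Degenerate one-label model (always predicts ``label`` with
        softmax 1). Not trainable via :func:`train_profile`, but needed
        where a candidate set collapses to one taxon."""
        return cls(k=k, labels=[label], vocab={}, log_probs=np.zeros((1, 0)))


def train_profile(
    reads_by_label: Mapping[int, Sequence[object]],
    k: int = 13,
    smoothing: float = 1.0,
) -> KmerProfileModel:
    """Train a :class:`KmerProfileModel` from per-label read collections.

    ``reads_by_label`` maps taxid to reads; each read may be a sequence
    string or a (mate1, mate2) pair. At least two labels are required and
    every label needs at least one read.
    """
    labels = sorted(reads_by_label)
    if len(labels) < 2:
        raise SingleLabelError("profile training needs >= 2 labels")
    counts: dict[int, dict[str, int]] = {}
    for label in labels:
        reads = reads_by_label[label]
        if not reads:
            raise EmptyInputError(f"label {label} has no training reads")
        c: dict[str, int] = {}
        for read in reads:
            pair = read if isinstance(read, tuple) else (read, None)
            toks, _ = _pair_tokens(pair, k)
            for tok in toks:
                c[tok] = c.get(tok, 0) + 1
        counts[label] = c
    vocab_tokens = sorted(set().union(*counts.values()))
    vocab = {tok: i for i, tok in enumerate(vocab_tokens)}
    v = len(vocab)
    log_probs = np.empty((len(labels), v))
    for row, label in enumerate(labels):
        vec = np.full(v, smoothing)
        for tok, n in counts[label].items():
            vec[vocab[tok]] += n
        log_probs[row] = np.log(vec / vec.sum())
    return KmerProfileModel(
        k=k, labels=labels, vocab=vocab, log_probs=log_probs,
        smoothing=smoothing,
    )


def predict_profile(
    model: KmerProfileModel,
    read_pair: ReadPair,
    allowed: Iterable[int] | None = None,
) -> tuple[int, float, dict[int, float]]:
    """Score a read pair under the profile model.

    Returns ``(argmax label, its softmax, per-label mean log-likelihoods)``;
    the softmax is normalized over ``allowed`` (all labels when None).
    Scores are length-normalized — the mean per-token log-likelihood rather
    than the sum — before the softmax: the normalization preserves the
    argmax but stops the softmax saturating as reads contribute hundreds of
    correlated tokens, which is what keeps a fixed confidence threshold
    meaningful across read lengths. Ties break deterministically toward
    the earlier label in model order.
    """
    if allowed is None:
        rows = list(range(len(model.labels)))
    else:
        allowed = set(allowed)
        rows = [i for i, lab in enumerate(model.labels) if lab in allowed]
        if not rows:
            raise EmptyAllowedError(
                "allowed set shares no labels with the model"
            )
    tokens, _ = _pair_tokens(read_pair, model.k)
    cols = [model.vocab[tok] for tok in tokens if tok in model.vocab]
    if cols:
        scores = model.log_probs[np.ix_(rows, cols)].sum(axis=1) / len(cols)
    else:
        scores = np.zeros(len(rows))
    probs = _softmax(scores)
    best = int(np.argmax(probs))  # argmax takes the first max -> model order
    score_map = {model.labels[r]: float(scores[i]) for i, r in enumerate(rows)}
    return model.labels[rows[best]], float(probs[best]), score_map


# ============================ best-hit aligner ==============================

class AlignIndex:
    """Seed-and-extend ungapped best-hit aligner over per-species references.

    Seeding uses exact ``seed_len`` matches on either strand; extension is
    ungapped with +1 match / -1 mismatch over the read's overlap with the
    reference. A read pair's score against a reference is the sum of each
    mate's best placement score.
    """

    def __init__(
        self, references: Mapping[int, Sequence[tuple[str, str]]],
        seed_len: int = 21,
    ):
        if not references:
            raise EmptyInputError("no references")
        for species, refs in references.items():
            if not refs:
                raise EmptyInputError(f"species {species} has no references")
        self.seed_len = seed_len
        self.references = {
            sp: [(rid, seq.upper()) for rid, seq in refs]
            for sp, refs in references.items()
        }
        # seed -> list of (species, ref index, position)
        self._seeds: dict[str, list[tuple[int, int, int]]] = {}
        for sp in sorted(self.references):
            for ri, (_, seq) in enumerate(self.references[sp]):
                for pos in range(len(seq) - seed_len + 1):
                    seed = seq[pos : pos + seed_len]
                    if "N" not in seed:
                        self._seeds.setdefault(seed, []).append((sp, ri, pos))

    def _mate_scores(self, mate: str) -> dict[tuple[int, int], int]:
        """Best placement score per (species, ref index) for one mate."""
        mate = _check_read(mate)
        best: dict[tuple[int, int], int] = {}
        for oriented in (mate, revcomp(mate)):
            diagonals: dict[tuple[int, int], set[int]] = {}
            for off in range(len(oriented) - self.seed_len + 1):
                seed = oriented[off : off + self.seed_len]
                for sp, ri, pos in self._seeds.get(seed, ()):
                    diagonals.setdefault((sp, ri), set()).add(pos - off)
            for (sp, ri), diags in diagonals.items():
                ref = self.references[sp][ri][1]
                for diag in diags:
                    score = 0
                    for i, base in enumerate(oriented):
                        rpos = diag + i
                        if 0 <= rpos < len(ref):
                            score += 1 if ref[rpos] == base else -1
                    key = (sp, ri)
                    if score > best.get(key, -math.inf):
                        best[key] = score
        return best


def best_hit(
    index: AlignIndex, read_pair: ReadPair
) -> tuple[int | None, float, bool]:
    """Best-scoring species for a read pair.

    Returns ``(species, score, tie)``: the top species by maximum reference
    score, that score, and whether >= 2 species share the maximum (the
    returned species is then the smallest tied taxid). ``(None, 0.0,
    False)`` when no seed matches anywhere.
    """
    per_ref: dict[tuple[int, int], float] = {}
    for mate in read_pair:
        if mate is None:
            continue
        for key, score in index._mate_scores(mate).items():
            per_ref[key] = per_ref.get(key, 0.0) + score
    if not per_ref:
        return None, 0.0, False
    per_species: dict[int, float] = {}
    for (sp, _), score in per_ref.items():
        per_species[sp] = max(per_species.get(sp, -math.inf), score)
    top = max(per_species.values())
    tied = sorted(sp for sp, s in per_species.items() if s == top)
    return tied[0], float(top), len(tied) > 1


# ============================= file interfaces ==============================

def _open_maybe_gz(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(
    r1_path, r2_path=None
) -> list[tuple[str, ReadPair]]:
    """Read (optionally gzipped) FASTQ into (read_id, (mate1, mate2)) tuples.

    With a single file, mate2 is None for every read. Trailing ``/1`` and
    ``/2`` mate suffixes are stripped from read ids, as the classifiers the
    output feeds treat a pair as one query.
    """
    from Bio import SeqIO

    def clean(rid: str) -> str:
        return rid[:-2] if rid.endswith(("/1", "/2")) else rid

    with _open_maybe_gz(r1_path) as fh:
        r1 = [(clean(rec.id), str(rec.seq).upper())
              for rec in SeqIO.parse(fh, "fastq")]
    if r2_path is None:
        return [(rid, (seq, None)) for rid, seq in r1]
    with _open_maybe_gz(r2_path) as fh:
        r2 = [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]
    if len(r1) != len(r2):
        raise FormatError("R1 and R2 read counts differ")
    return [(rid, (s1, s2)) for (rid, s1), s2 in zip(r1, r2)]


def parse_predictions(
    path,
    dialect: str,
    t: Taxonomy,
    ref_taxa: Mapping[str, int] | None = None,
    on_unknown: str = "error",
    source: str | None = None,
) -> list[Prediction]:
    """Parse external classifier output into :class:`Prediction` objects.

    Dialects: ``kraken2`` (``status read_id taxid read_len kmer_map``),
    ``kaiju`` (``status read_id taxid``), ``sam`` (best primary alignment
    per read by the ``AS`` tag; equal-best hits across species collapse to
    the LCA of the tied species), and ``native`` (this package's own TSV).
    Taxids outside the taxonomy raise :class:`UnknownTaxonError`, or are
    skipped with ``on_unknown="skip"``. SAM reference names map to species
    through ``ref_taxa`` or, failing that, a leading ``<taxid>|`` prefix.
    """
    if dialect == "sam":
        return _parse_sam(path, t, ref_taxa, source or "sam")
    if dialect not in ("kraken2", "kaiju", "native"):
        raise FormatError(f"unknown dialect {dialect!r}")
    src = source or dialect
    preds: list[Prediction] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "native":
                    read_id, status, taxid_s, rank, conf, psrc = parts
                    if status == "U":
                        preds.append(Prediction.unclassified(read_id, psrc))
                        continue
                    taxid = int(taxid_s)
                    confidence = None if conf == "-" else float(conf)
                else:
                    min_cols = 5 if dialect == "kraken2" else 3
                    if len(parts) < min_cols:
                        raise ValueError(f"expected >= {min_cols} columns")
                    status, read_id, taxid_s = parts[0], parts[1], parts[2]
                    if status not in ("C", "U"):
                        raise ValueError(f"bad status {status!r}")
                    taxid = int(taxid_s)
                    confidence = None
                    if status == "U" or taxid == 0:
                        preds.append(Prediction.unclassified(read_id, src))
                        continue
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from err
            if taxid not in t:
                if on_unknown == "skip":
                    continue
                raise UnknownTaxonError(
                    f"{path}:{lineno}: taxid {taxid} not in taxonomy"
                )
            preds.append(
                Prediction(read_id, taxid, t.rank_of(taxid), confidence,
                           psrc if dialect == "native" else src)
            )
    return preds


def _parse_sam(path, t: Taxonomy, ref_taxa, source) -> list[Prediction]:
    import pysam

    def species_of(refname: str) -> int:
        if ref_taxa is not None and refname in ref_taxa:
            return ref_taxa[refname]
        head = refname.split("|", 1)[0]
        try:
            return int(head)
        except ValueError:
            raise FormatError(
                f"cannot map SAM reference {refname!r} to a taxid"
            ) from None

    best: dict[str, tuple[float, set[int]]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            qname = aln.query_name
            if qname not in best:
                best[qname] = (-math.inf, set())
                order.append(qname)
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            score = float(aln.get_tag("AS")) if aln.has_tag("AS") else 0.0
            sp = species_of(aln.reference_name)
            if sp not in t:
                raise UnknownTaxonError(f"SAM taxid {sp} not in taxonomy")
            cur_score, cur_set = best[qname]
            if score > cur_score:
                best[qname] = (score, {sp})
            elif score == cur_score:
                cur_set.add(sp)
    preds = []
    for qname in order:
        _, species = best[qname]
        if not species:
            preds.append(Prediction.unclassified(qname, source))
        else:
            taxon = next(iter(species)) if len(species) == 1 else t.lca(species)
            preds.append(
                Prediction(qname, taxon, t.rank_of(taxon), None, source)
            )
    return preds


def write_predictions(
    preds: Sequence[Prediction], path, dialect: str = "native"
) -> None:
    """Write predictions as TSV in the ``native``, ``kraken2`` or ``kaiju``
    dialect (the external dialects drop fields they cannot carry)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in preds:
            if dialect == "native":
                conf = "-" if p.confidence is None else repr(p.confidence)
                if p.is_unclassified:
                    fh.write(f"{p.read_id}\tU\t0\t-\t-\t{p.source}\n")
                else:
                    fh.write(
                        f"{p.read_id}\tC\t{p.taxon}\t{p.rank}\t{conf}\t"
                        f"{p.source}\n"
                    )
            elif dialect == "kraken2":
                if p.is_unclassified:
                    fh.write(f"U\t{p.read_id}\t0\t0\t-\n")
                else:
                    fh.write(f"C\t{p.read_id}\t{p.taxon}\t0\t-\n")
            elif dialect == "kaiju":
                status, taxid = ("U", 0) if p.is_unclassified else ("C", p.taxon)
                fh.write(f"{status}\t{p.read_id}\t{taxid}\n")
            else:
                raise FormatError(f"unknown dialect {dialect!r}")
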