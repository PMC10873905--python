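"""Reproducible validation experiments on synthetic communities.

Each function builds its own inputs with the :mod:`taxoclass.simulate`
generator (or a hand-constructed fixture documented inline), runs the
relevant pipeline stages, and returns plain numbers. They back both the
acceptance test suite and ``scripts/acceptance.py``, so every reported
figure is recomputed from scratch at run time.
"""

from __future__ import annotations

import copy

import numpy as np

from . import simulate as sim
from .classify import Prediction, build_lca_index, classify_lca
from .curation import (
    AssemblyRecord,
    ClusterParams,
    curate_species,
    mean_silhouette,
    optics_cluster,
)
from .evaluate import confusion_at_rank, mcc, unseen_fp_rate
from .hierarchy import (
    StrategySpec,
    assemble,
    count_models,
    ensemble_primary_specialist,
    train_components,
)
from .simulate import (
    DEFAULT_DIVERGENCE,
    SimulationConfig,
    TaxonomyShape,
    evolve_genomes,
    label_reads,
    simulate_reads,
    synth_taxonomy,
)
from .taxonomy import Taxonomy


# ------------------------- model-count accounting ---------------------------

def model_count_summary(shape: TaxonomyShape = TaxonomyShape(2, 1, 1, 1, 2, 3),
                        seed: int = 0) -> dict[str, int]:
    """Models each strategy needs on a 6-rank taxonomy."""
    t = synth_taxonomy(shape, seed)
    return {
        "lcl": count_models(StrategySpec("lcl"), t),
        "hi_lcl": count_models(StrategySpec("hi_lcl"), t),
        "flat": count_models(StrategySpec("flat"), t),
        "lcpn": count_models(StrategySpec("lcpn"), t),
        "lcl_lcpn": count_models(StrategySpec("lcl_lcpn"), t),
    }


# --------------------------- MCC oracle check -------------------------------

def _one_hot_corr(counts: np.ndarray) -> float:
    """Correlation between column-centered one-hot truth/prediction
    encodings — the brute-force reference for the confusion-matrix MCC."""
    k = counts.shape[0]
    n = int(counts.sum())
    x = np.zeros((n, k))
    y = np.zeros((n, k))
    row = 0
    for i in range(k):
        for j in range(k):
            for _ in range(int(counts[i, j])):
                x[row, i] = 1.0
                y[row, j] = 1.0
                row += 1
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    den = np.sqrt((xc * xc).sum()) * np.sqrt((yc * yc).sum())
    return float((xc * yc).sum() / den) if den > 0 else 0.0


def mcc_oracle_deviation(n_matrices: int = 200, seed: int = 0) -> float:
    """Max |MCC - one-hot-correlation oracle| over random confusion
    matrices (K <= 6, counts <= 50)."""
    from .evaluate import ConfusionMatrix, UNCLASSIFIED

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x6D6363])
    worst = 0.0
    done = 0
    while done < n_matrices:
        k = int(rng.integers(2, 7))
        counts = rng.integers(0, 51, size=(k, k))
        if counts.sum() == 0:
            continue
        full = np.zeros((k + 1, k + 1), dtype=int)
        full[:k, :k] = counts
        cm = ConfusionMatrix(list(range(k)) + [UNCLASSIFIED], full)
        worst = max(worst, abs(mcc(cm) - _one_hot_corr(full)))
        done += 1
    return worst


# -------------------------- ensemble rule forcing ---------------------------

class _FixedSpecialist:
    """Specialist stub with a preset softmax outcome (rule-forcing only)."""

    def __init__(self, labels, winner, score):
        self.labels = sorted(labels)
        self._winner = winner
        self._score = score

    def predict(self, read_pair, allowed=None):
        return self._winner, self._score, {}


def ensemble_rule_examples(seed: int = 0) -> int:
    """Run the forcing examples of the three ensemble rules; returns how
    many behave as specified (out of 9)."""
    from .hierarchy import ensemble_primary_align, ensemble_union
    from .classify import AlignIndex

    t = synth_taxonomy(TaxonomyShape(1, 1, 1, 1, 2, 3), seed)
    genus = t.taxa_at_rank("genus")[0]
    s1, s2, s3 = t.children_of(genus)
    family = t.taxa_at_rank("family")[0]
    spec = StrategySpec("primary_specialist")
    read = ("ACGTACGTACGTACGTACGTACGT", None)
    passed = 0

    def specialist_model(winner, score):
        specialists = {
            g: _FixedSpecialist(t.children_of(g), winner, score)
            for g in t.taxa_at_rank("genus")
        }
        return assemble(spec, {"primary": object(),
                               "specialists": specialists}, t)

    prim_genus = Prediction("r", genus, "genus", None, "primary")
    # specialist rule: confident specialist wins ...
    out = ensemble_primary_specialist(prim_genus, specialist_model(s1, 0.6), read)
    passed += out.taxon == s1 and out.rank == "species"
    # ... a weak one falls back to the primary's own call ...
    out = ensemble_primary_specialist(prim_genus, specialist_model(s1, 0.4), read)
    passed += out == prim_genus
    # ... and an unclassified primary stays unclassified.
    out = ensemble_primary_specialist(
        Prediction.unclassified("r", "primary"), specialist_model(s1, 0.9), read
    )
    passed += out.is_unclassified

    rng = np.random.default_rng(seed + 17)
    ref1 = "".join(rng.choice(list("ACGT"), size=400))
    ref2 = "".join(rng.choice(list("ACGT"), size=400))
    align_spec = StrategySpec("primary_align")

    def align_model(refs_by_species):
        specialists = {}
        for g in t.taxa_at_rank("genus"):
            specialists[g] = AlignIndex({
                s: [(f"{s}", refs_by_species.get(s, ref2))]
                for s in t.children_of(g)
            })
        return assemble(align_spec, {"primary": object(),
                                     "specialists": specialists}, t)

    # align rule: unique best species wins ...
    m = align_model({s1: ref1})
    out = ensemble_primary_align(prim_genus, m, (ref1[50:200], None))
    passed += out.taxon == s1 and out.rank == "species"
    # ... a cross-species score tie falls back ...
    m = align_model({})  # every species holds ref2 -> tie
    out = ensemble_primary_align(prim_genus, m, (ref2[50:200], None))
    passed += out == prim_genus
    # ... and a primary stopped above genus passes through untouched.
    prim_family = Prediction("r", family, "family", None, "primary")
    out = ensemble_primary_align(prim_family, align_model({s1: ref1}),
                                 (ref1[50:200], None))
    passed += out == prim_family

    # union rule precedence
    sp_a = Prediction("r", s1, "species", None, "a")
    sp_b = Prediction("r", s2, "species", None, "b")
    gen_a = Prediction("r", genus, "genus", None, "a")
    gen_b = Prediction("r", genus, "genus", None, "b")
    passed += ensemble_union(sp_a, sp_b, t) == sp_a
    passed += ensemble_union(gen_a, sp_b, t) == sp_b
    passed += ensemble_union(gen_a, gen_b, t) == gen_a
    return int(passed)


# ------------------------------ LCA safety ----------------------------------

def lca_safety_experiment(seed: int = 0) -> dict[str, float]:
    """Error-free reads from curated references on a (2,1,1,1,2,3)
    community: count ancestor-or-self violations, and check that reads from
    sequence shared verbatim by sister species land exactly on the genus.
    """
    cfg = SimulationConfig(shape=TaxonomyShape(2, 1, 1, 1, 2, 3),
                           error_rate=0.0, seed=seed,
                           reads_per_species=150)
    t = synth_taxonomy(cfg.shape, seed)
    com = evolve_genomes(t, cfg)
    curated = curate_species(
        [r for v in com.train_assemblies.values() for r in v]
    )
    # inject a conserved sequence shared verbatim by each genus's sisters
    rng = sim.stage_rng(seed, "shared")
    shared_by_genus = {}
    for genus in t.taxa_at_rank("genus"):
        shared = "".join(rng.choice(list("ACGT"), size=1200))
        shared_by_genus[genus] = shared
        for sp in t.children_of(genus):
            curated[sp] = curated[sp] + [shared]
    index = build_lca_index(curated, t, k=21)

    curated_assemblies = {
        sp: [AssemblyRecord(accession=f"C{sp}", species=sp,
                            assembly_level="contig", sequences=seqs)]
        for sp, seqs in curated.items()
    }
    reads = simulate_reads(curated_assemblies, cfg, stage="safety")
    violations = 0
    for pair, sp in reads:
        pred = classify_lca(index, pair)
        if pred.is_unclassified or pred.taxon not in t.root_path(sp):
            violations += 1

    genus_exact = 0
    genus_total = 0
    for genus, shared in shared_by_genus.items():
        for start in range(0, len(shared) - 300, 60):
            frag = shared[start:start + 300]
            pred = classify_lca(index, (frag[:150], sim.revcomp(frag[-150:])))
            genus_total += 1
            genus_exact += pred.taxon == genus
    return {
        "n_reads": len(reads),
        "violations": violations,
        "shared_read_genus_rate": genus_exact / genus_total,
    }


# ------------------------- redundancy removal -------------------------------

def redundancy_experiment(seed: int = 0) -> dict[str, float]:
    """Strain-redundant panels: verbatim triplication must not change the
    curated output or the index, while skipping curation inflates the
    stored k-mer entries.

    Two species, 20 strain assemblies each at 0.4% strain divergence —
    the regime where the per-species cap, representative selection and the
    99% coding-sequence dedup all engage.
    """
    t = synth_taxonomy(TaxonomyShape(1, 1, 1, 1, 1, 2), seed)
    species = t.taxa_at_rank("species")
    rng = sim.stage_rng(seed, "redundancy")
    records = []
    for sp in species:
        base = rng.integers(0, 4, size=12_000, dtype=np.uint8)
        bounds = sim._segment_bounds(12_000, rng)
        for i in range(20):
            genome = sim._mutate(base, 0.004, rng)
            records.append(AssemblyRecord(
                accession=f"A{sp}.{i:02d}", species=sp,
                assembly_level="scaffold", refseq_category="na",
                strain=f"strain-{sp}-{i}",
                n50=int(rng.integers(100_000, 2_000_000)),
                sequences=[sim._to_str(genome[a:b]) for a, b in bounds],
            ))
    tripled = list(records)
    for rec in records:
        for j in (1, 2):
            dup = copy.deepcopy(rec)
            dup.accession = f"{rec.accession}~dup{j}"
            tripled.append(dup)

    curated = curate_species(records)
    curated_tripled = curate_species(tripled)
    index = build_lca_index(curated, t, k=21)
    index_tripled = build_lca_index(curated_tripled, t, k=21)
    pooled = {}
    for rec in tripled:
        pooled.setdefault(rec.species, []).extend(rec.sequences)
    index_pooled = build_lca_index(pooled, t, k=21)
    return {
        "curation_identical": float(curated == curated_tripled),
        "index_identical": float(index.table == index_tripled.table),
        "uncurated_inflation": len(index_pooled) / len(index),
    }


# -------------------------- rank asymmetry ----------------------------------

def rank_asymmetry_experiment(seed: int) -> dict[str, float]:
    """One confusable-sister replicate: curate, index, train specialists,
    classify held-out reads; species/genus MCC for the flat classifier and
    species MCC for the primary+specialist ensemble."""
    div = dict(DEFAULT_DIVERGENCE)
    div["species"] = 0.005
    cfg = SimulationConfig(shape=TaxonomyShape(1, 1, 1, 1, 2, 3),
                           divergence=div, seed=seed)
    t = synth_taxonomy(cfg.shape, seed)
    com = evolve_genomes(t, cfg)
    curated = curate_species(
        [r for v in com.train_assemblies.values() for r in v]
    )
    index = build_lca_index(curated, t, k=21)
    train = simulate_reads(com.train_assemblies, cfg, stage="train")
    by_sp: dict[int, list] = {}
    for pair, sp in train:
        by_sp.setdefault(sp, []).append(pair)
    spec = StrategySpec("primary_specialist")
    comp = train_components(by_sp, t, spec,
                            balance_n=cfg.reads_per_species, seed=seed)
    comp["primary"] = index
    model = assemble(spec, comp, t)
    test_cfg = SimulationConfig(shape=cfg.shape, divergence=div, seed=seed,
                                reads_per_species=200)
    labelled, truth = label_reads(
        simulate_reads(com.test_assemblies, test_cfg)
    )
    flat = [classify_lca(index, pair, read_id=rid) for rid, pair in labelled]
    ens = [ensemble_primary_specialist(p, model, pair)
           for p, (rid, pair) in zip(flat, labelled)]
    return {
        "flat_species_mcc": mcc(confusion_at_rank(truth, flat, t, "species")),
        "flat_genus_mcc": mcc(confusion_at_rank(truth, flat, t, "genus")),
        "ensemble_species_mcc": mcc(
            confusion_at_rank(truth, ens, t, "species")
        ),
    }


# --------------------------- unseen-taxa FP ---------------------------------

def unseen_taxa_experiment(seed: int = 0) -> dict[str, float]:
    """Species false-positive rate on reads from a species absent from the
    reference, with LCA storage on vs off.

    The fixture models the driver of such false positives in real data: a
    conserved core (identical across the genus, like housekeeping operons)
    plus species-specific accessory sequence. The unseen sister shares
    only the core with the indexed species.
    """
    t = synth_taxonomy(TaxonomyShape(1, 1, 1, 1, 1, 3), seed)
    s1, s2, s3 = t.taxa_at_rank("species")
    rng = sim.stage_rng(seed, "unseen")
    core = sim._to_str(rng.integers(0, 4, size=6000, dtype=np.uint8))
    accessory = {
        sp: sim._to_str(rng.integers(0, 4, size=6000, dtype=np.uint8))
        for sp in (s1, s2, s3)
    }
    refs = {sp: [core, accessory[sp]] for sp in (s1, s2)}
    cfg = SimulationConfig(shape=TaxonomyShape(1, 1, 1, 1, 1, 3),
                           reads_per_species=400, seed=seed)
    unseen_rec = AssemblyRecord(accession=f"T{s3}", species=s3,
                                assembly_level="contig",
                                sequences=[core, accessory[s3]])
    labelled, truth = label_reads(simulate_reads({s3: [unseen_rec]}, cfg))
    out = {}
    for name, lca_storage in (("lca", True), ("nolca", False)):
        index = build_lca_index(refs, t, k=21, lca_storage=lca_storage)
        preds = [classify_lca(index, pair, read_id=rid)
                 for rid, pair in labelled]
        out[name] = unseen_fp_rate(truth, preds, {"species": {s1, s2}},
                                   t, "species")
    return {"fp_rate_lca": out["lca"], "fp_rate_nolca": out["nolca"]}


# ------------------------- clustering oracle --------------------------------

def _density_oracle(d: np.ndarray, eps: float = 0.05,
                    min_samples: int = 2) -> list[int]:
    n = len(d)
    core = [(d[i] <= eps).sum() >= min_samples for i in range(n)]
    labels = [-1] * n
    cluster = 0
    for i in range(n):
        if core[i] and labels[i] == -1:
            stack = [i]
            labels[i] = cluster
            while stack:
                u = stack.pop()
                for v in range(n):
                    if d[u][v] <= eps and labels[v] == -1:
                        labels[v] = cluster
                        if core[v]:
                            stack.append(v)
            cluster += 1
    return labels


def _canon(labels) -> list[int]:
    seen: dict[int, int] = {}
    out = []
    for lab in labels:
        out.append(-1 if lab == -1 else seen.setdefault(lab, len(seen)))
    return out


def clustering_oracle_experiment() -> dict[str, float]:
    """OPTICS vs the brute-force density oracle on every block-structured
    dissimilarity matrix of up to 8 points, plus the silhouette of the
    perfectly separated 4-point fixture."""
    def partitions(n, mx):
        if n == 0:
            yield []
            return
        for k in range(min(n, mx), 0, -1):
            for rest in partitions(n - k, k):
                yield [k] + rest

    params = ClusterParams(max_eps=0.1)
    total = agree = 0
    for n in range(2, 9):
        for sizes in partitions(n, n):
            for intra in (0.0, 0.05):
                d = np.full((n, n), 0.5)
                pos = 0
                for s in sizes:
                    d[pos:pos + s, pos:pos + s] = intra
                    pos += s
                np.fill_diagonal(d, 0)
                total += 1
                agree += (_canon(optics_cluster(d, params))
                          == _canon(_density_oracle(d)))
    sep = np.array([
        [0.0, 0.0, 1.0, 1.0],
        [0.0, 0.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 0.0],
        [1.0, 1.0, 0.0, 0.0],
    ])
    silhouette = mean_silhouette(sep, [0, 0, 1, 1])
    return {
        "n_matrices": total,
        "oracle_agreement": agree / total,
        "separated_silhouette": silhouette,
    }
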