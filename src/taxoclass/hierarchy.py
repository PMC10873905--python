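"""Hierarchical classification strategies and ensemble rules.

Four strategies exploit the taxonomy during prediction:

* ``lcl``  — local classifier per level: one multi-class model per rank,
  ranks predicted independently;
* ``hi_lcl`` — hierarchy-informed LCL: the same per-rank models, but each
  rank's candidate set is restricted to children of the previous rank's
  prediction (softmax renormalized over the restriction);
* ``lcpn`` — local classifier per parent node: one model per internal node,
  routed top-down;
* ``lcl_lcpn`` — hybrid: LCL through family, then per-node models for genus
  and species (limiting hierarchy-informed routing to the lower ranks,
  where it helps, avoids the compounding of upper-rank errors).

Three ensemble rules combine a primary (reference-style) classifier with
specialists:

* primary + per-genus profile specialist with a softmax-threshold fallback
  to the primary's lowest-rank prediction;
* primary + per-genus best-hit aligner with an unmapped/tie fallback;
* union of two flat classifiers with species-level precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import (
    AlignIndex,
    KmerProfileModel,
    Prediction,
    ReadPair,
    best_hit,
    train_profile,
)
from .errors import MissingModelError
from .taxonomy import RANK_DEPTH, SUB_ROOT_RANKS, Taxonomy

STRATEGIES = (
    "lcl",
    "hi_lcl",
    "lcpn",
    "lcl_lcpn",
    "primary_specialist",
    "primary_align",
    "union",
    "flat",
)

MODEL_POLICIES = ("multichild_only", "all_parents")


@dataclass(frozen=True)
class StrategySpec:
    strategy: str
    threshold: float = 0.5
    switch_rank: str = "genus"
    model_policy: str = "multichild_only"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.model_policy not in MODEL_POLICIES:
            raise ValueError(f"unknown model_policy {self.model_policy!r}")
        if self.switch_rank not in RANK_DEPTH:
            raise ValueError(f"unknown rank {self.switch_rank!r}")
        if (self.strategy == "lcl_lcpn"
                and RANK_DEPTH[self.switch_rank] <= RANK_DEPTH["family"]):
            raise ValueError(
                "lcl_lcpn switches to per-node models below family"
            )


@dataclass
class HierarchicalModel:
    """Validated bundle of component classifiers for one strategy."""

    spec: StrategySpec
    taxonomy: Taxonomy
    rank_models: dict[str, KmerProfileModel] = field(default_factory=dict)
    node_models: dict[int, KmerProfileModel] = field(default_factory=dict)
    primary: object | None = None
    specialists: dict[int, object] = field(default_factory=dict)


def _parents_needing_model(
    t: Taxonomy, ranks: Sequence[str], policy: str
) -> list[int]:
    """Internal nodes at the given parent ranks that need a child-routing
    model (all of them, or only those with >= 2 children)."""
    out = []
    for rank in ranks:
        nodes = [t.root] if rank == "root" else t.taxa_at_rank(rank)
        for node in nodes:
            kids = t.children_of(node)
            if policy == "all_parents" or len(kids) > 1:
                out.append(node)
    return sorted(out)


def _lcpn_parent_ranks() -> list[str]:
    """Parent ranks for full LCPN routing: root..genus."""
    return ["root"] + list(SUB_ROOT_RANKS[:-1])


def assemble(
    spec: StrategySpec,
    components: Mapping[str, object],
    t: Taxonomy,
) -> HierarchicalModel:
    """Validate that ``components`` covers every model ``spec`` requires.

    ``components`` keys: ``rank_models``, ``node_models``, ``primary``,
    ``specialists``. Raises :class:`MissingModelError` naming every absent
    rank or parent node.
    """
    m = HierarchicalModel(
        spec=spec,
        taxonomy=t,
        rank_models=dict(components.get("rank_models", {})),
        node_models=dict(components.get("node_models", {})),
        primary=components.get("primary"),
        specialists=dict(components.get("specialists", {})),
    )
    missing: list[str] = []
    strategy = spec.strategy

    def need_ranks(ranks):
        for rank in ranks:
            if rank not in m.rank_models:
                missing.append(f"rank:{rank}")

    def need_nodes(parents):
        for node in parents:
            model = m.node_models.get(node)
            if model is None:
                missing.append(f"node:{node}")
            else:
                kids = set(t.children_of(node))
                if set(model.labels) != kids:
                    raise MissingModelError(
                        f"node {node}: model labels {sorted(model.labels)} "
                        f"!= children {sorted(kids)}"
                    )

    if strategy in ("lcl", "hi_lcl"):
        need_ranks(SUB_ROOT_RANKS)
    elif strategy == "lcpn":
        need_nodes(_parents_needing_model(t, _lcpn_parent_ranks(),
                                          spec.model_policy))
    elif strategy == "lcl_lcpn":
        upper = [r for r in SUB_ROOT_RANKS
                 if RANK_DEPTH[r] < RANK_DEPTH[spec.switch_rank]]
        need_ranks(upper)
        parent_ranks = SUB_ROOT_RANKS[
            RANK_DEPTH[spec.switch_rank] - 2 : -1
        ]
        need_nodes(_parents_needing_model(t, parent_ranks, spec.model_policy))
    elif strategy in ("primary_specialist", "primary_align"):
        if m.primary is None:
            missing.append("primary")
        for genus in _specialist_genera(t, spec.model_policy):
            if genus not in m.specialists:
                missing.append(f"genus:{genus}")
    elif strategy == "union":
        pass  # combines two prediction streams; no trained components
    if missing:
        raise MissingModelError("missing components: " + ", ".join(missing))
    return m


def _specialist_genera(t: Taxonomy, policy: str) -> list[int]:
    return [
        g for g in t.taxa_at_rank("genus")
        if policy == "all_parents" or len(t.children_of(g)) > 1
    ]


# ------------------------------ strategies ----------------------------------

def predict_lcl(
    m: HierarchicalModel, read_pair: ReadPair, read_id: str = ""
) -> dict[str, Prediction]:
    """Independent per-rank predictions; sub-threshold ranks are
    unclassified. No cross-rank consistency is enforced."""
    out: dict[str, Prediction] = {}
    for rank in SUB_ROOT_RANKS:
        model = m.rank_models[rank]
        label, p, _ = model.predict(read_pair)
        if p < m.spec.threshold:
            out[rank] = Prediction.unclassified(read_id, f"lcl:{rank}")
        else:
            out[rank] = Prediction(read_id, label, rank, p, f"lcl:{rank}")
    return out


def headline(per_rank: Mapping[str, Prediction], read_id: str = "",
             source: str = "lcl") -> Prediction:
    """Deepest classified prediction of an LCL-style per-rank map."""
    for rank in reversed(SUB_ROOT_RANKS):
        p = per_rank.get(rank)
        if p is not None and not p.is_unclassified:
            return p
    return Prediction.unclassified(read_id, source)


def predict_hi_lcl(
    m: HierarchicalModel, read_pair: ReadPair, read_id: str = ""
) -> list[Prediction]:
    """Top-down restricted LCL: each rank's candidates are the children of
    the previous prediction, softmax renormalized over the restriction;
    descent stops at a sub-threshold score or an empty restriction. The
    returned path is ancestor-consistent by construction."""
    path: list[Prediction] = []
    prev: int | None = None
    t = m.taxonomy
    for rank in SUB_ROOT_RANKS:
        model = m.rank_models[rank]
        if prev is None:
            allowed = None
        else:
            allowed = t.children_at(prev, rank) & set(model.labels)
            if not allowed:
                break
        label, p, _ = model.predict(read_pair, allowed)
        if p < m.spec.threshold:
            break
        path.append(Prediction(read_id, label, rank, p, f"hi_lcl:{rank}"))
        prev = label
    return path


def predict_lcpn(
    m: HierarchicalModel, read_pair: ReadPair, read_id: str = ""
) -> list[Prediction]:
    """Top-down per-parent-node routing from the root; single-child parents
    pass through with confidence 1 under ``multichild_only``."""
    t = m.taxonomy
    path: list[Prediction] = []
    cur = t.root
    for rank in SUB_ROOT_RANKS:
        kids = t.children_of(cur)
        if not kids:
            break
        if len(kids) == 1 and m.spec.model_policy == "multichild_only":
            label, p = kids[0], 1.0
        else:
            model = m.node_models.get(cur)
            if model is None:
                raise MissingModelError(f"no node model for parent {cur}")
            label, p, _ = model.predict(read_pair)
        if p < m.spec.threshold:
            break
        path.append(Prediction(read_id, label, rank, p, "lcpn"))
        cur = label
    return path


def predict_lcl_lcpn(
    m: HierarchicalModel, read_pair: ReadPair, read_id: str = ""
) -> list[Prediction]:
    """Hybrid: independent rank models through family, then per-node models
    for genus and species.

    The headline is the deepest classified taxon; the returned path is its
    ancestor chain, carrying model confidences at the ranks where a model
    scored that exact taxon.
    """
    t = m.taxonomy
    spec = m.spec
    upper_ranks = [r for r in SUB_ROOT_RANKS
                   if RANK_DEPTH[r] < RANK_DEPTH[spec.switch_rank]]
    upper: dict[str, tuple[int, float]] = {}
    for rank in upper_ranks:
        label, p, _ = m.rank_models[rank].predict(read_pair)
        if p >= spec.threshold:
            upper[rank] = (label, p)
    deepest_taxon: int | None = None
    conf_at: dict[int, float] = {}
    for rank in upper_ranks:
        if rank in upper:
            deepest_taxon = upper[rank][0]
            conf_at[deepest_taxon] = upper[rank][1]
    if deepest_taxon is None:
        return []
    # descend through per-node models only from a classified family
    if upper_ranks[-1] in upper:
        cur = upper[upper_ranks[-1]][0]
        for rank in SUB_ROOT_RANKS[len(upper_ranks):]:
            kids = t.children_of(cur)
            if not kids:
                break
            if len(kids) == 1 and spec.model_policy == "multichild_only":
                label, p = kids[0], 1.0
            else:
                model = m.node_models.get(cur)
                if model is None:
                    raise MissingModelError(f"no node model for parent {cur}")
                label, p, _ = model.predict(read_pair)
            if p < spec.threshold:
                break
            conf_at[label] = p
            deepest_taxon = label
            cur = label
    path: list[Prediction] = []
    for rank in SUB_ROOT_RANKS:
        anc = t.project(deepest_taxon, rank)
        if anc is None:
            break
        path.append(
            Prediction(read_id, anc, rank, conf_at.get(anc), "lcl_lcpn")
        )
    return path


# ------------------------------- ensembles ----------------------------------

def ensemble_primary_specialist(
    primary_pred: Prediction,
    m: HierarchicalModel,
    read_pair: ReadPair,
) -> Prediction:
    """Route the read to the per-genus specialist named by the primary's
    genus-level prediction; below-threshold specialist scores fall back to
    the primary's own lowest-rank prediction. An unclassified primary stays
    unclassified, and a primary that never reaches genus (or a genus with
    no specialist) passes through untouched."""
    if primary_pred.is_unclassified:
        return primary_pred
    genus = m.taxonomy.project(primary_pred.taxon, "genus")
    if genus is None or genus not in m.specialists:
        return primary_pred
    model = m.specialists[genus]
    label, p, _ = model.predict(read_pair)
    if p >= m.spec.threshold:
        return Prediction(
            primary_pred.read_id, label, "species", p, "specialist"
        )
    return primary_pred


def ensemble_primary_align(
    primary_pred: Prediction,
    m: HierarchicalModel,
    read_pair: ReadPair,
) -> Prediction:
    """As the specialist ensemble, but the per-genus refiner is a best-hit
    aligner: a unique top species wins; an unmapped read or a cross-species
    score tie falls back to the primary's lowest-rank prediction."""
    if primary_pred.is_unclassified:
        return primary_pred
    genus = m.taxonomy.project(primary_pred.taxon, "genus")
    if genus is None or genus not in m.specialists:
        return primary_pred
    index: AlignIndex = m.specialists[genus]
    species, _score, tie = best_hit(index, read_pair)
    if species is None or tie:
        return primary_pred
    return Prediction(primary_pred.read_id, species, "species", None, "align")


def ensemble_union(
    primary_pred: Prediction,
    secondary_pred: Prediction,
    t: Taxonomy,
) -> Prediction:
    """Species-level precedence union: the primary's species call wins; the
    secondary's species call substitutes when the primary has none; else
    the primary's lowest-rank prediction (possibly unclassified) stands."""
    if primary_pred.rank == "species":
        return primary_pred
    if secondary_pred.rank == "species":
        return secondary_pred
    return primary_pred


# ---------------------------- model accounting ------------------------------

def count_models(spec: StrategySpec, t: Taxonomy) -> int:
    """Number of trained models the strategy requires on taxonomy ``t``."""
    s = spec.strategy
    if s in ("lcl", "hi_lcl"):
        return len(SUB_ROOT_RANKS)
    if s == "flat":
        return 1
    if s == "lcpn":
        return len(_parents_needing_model(t, _lcpn_parent_ranks(),
                                          spec.model_policy))
    if s == "lcl_lcpn":
        upper = RANK_DEPTH[spec.switch_rank] - 1
        parent_ranks = SUB_ROOT_RANKS[RANK_DEPTH[spec.switch_rank] - 2 : -1]
        return upper + len(
            _parents_needing_model(t, parent_ranks, spec.model_policy)
        )
    if s in ("primary_specialist", "primary_align"):
        return 1 + len(_specialist_genera(t, spec.model_policy))
    if s == "union":
        return 2
    raise ValueError(s)


# ---------------------------- training harness ------------------------------

def _balanced(
    reads: Sequence[object], n: int | None, rng: np.random.Generator
) -> list[object]:
    if n is None or len(reads) <= n:
        return list(reads)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]


def train_components(
    reads_by_species: Mapping[int, Sequence[object]],
    t: Taxonomy,
    spec: StrategySpec,
    k: int = 13,
    smoothing: float = 1.0,
    balance_n: int | None = None,
    seed: int = 0,
) -> dict[str, object]:
    """Train every profile-model component a strategy needs.

    Training reads are grouped per species; higher-rank models pool the
    reads of their descendant species. ``balance_n`` caps the per-species
    read count by seeded down-sampling before any grouping, so specialists
    see an approximately equal number of reads per species and are not
    biased toward over-represented taxa.
    """
    rng = np.random.default_rng(seed)
    balanced = {
        sp: _balanced(reads, balance_n, rng)
        for sp, reads in sorted(reads_by_species.items())
    }

    def group_model(groups: dict[int, list[object]]) -> KmerProfileModel:
        groups = {lab: reads for lab, reads in groups.items() if reads}
        if len(groups) == 1:
            (label,) = groups
            return KmerProfileModel.single_label(label, k=k)
        return train_profile(groups, k=k, smoothing=smoothing)

    def reads_under(taxon: int) -> list[object]:
        node_rank = t.rank_of(taxon)
        if node_rank == "species":
            return list(balanced.get(taxon, []))
        out: list[object] = []
        for sp in balanced:
            if t.project(sp, node_rank) == taxon:
                out.extend(balanced[sp])
        return out

    components: dict[str, object] = {}
    strategy = spec.strategy

    if strategy in ("lcl", "hi_lcl", "lcl_lcpn"):
        if strategy == "lcl_lcpn":
            ranks = [r for r in SUB_ROOT_RANKS
                     if RANK_DEPTH[r] < RANK_DEPTH[spec.switch_rank]]
        else:
            ranks = list(SUB_ROOT_RANKS)
        rank_models = {}
        for rank in ranks:
            groups: dict[int, list[object]] = {}
            for sp in balanced:
                label = t.project(sp, rank)
                if label is not None:
                    groups.setdefault(label, []).extend(balanced[sp])
            rank_models[rank] = group_model(groups)
        components["rank_models"] = rank_models

    if strategy in ("lcpn", "lcl_lcpn"):
        if strategy == "lcpn":
            parent_ranks = _lcpn_parent_ranks()
        else:
            parent_ranks = SUB_ROOT_RANKS[RANK_DEPTH[spec.switch_rank] - 2 : -1]
        node_models = {}
        for parent in _parents_needing_model(t, parent_ranks,
                                             spec.model_policy):
            groups = {kid: reads_under(kid) for kid in t.children_of(parent)}
            node_models[parent] = group_model(groups)
        components["node_models"] = node_models

    if strategy in ("primary_specialist", "primary_align"):
        specialists = {}
        for genus in _specialist_genera(t, spec.model_policy):
            groups = {sp: list(balanced.get(sp, []))
                      for sp in t.children_of(genus)}
            specialists[genus] = group_model(groups)
        components["specialists"] = specialists

    return components
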