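"""Hierarchical strategies, ensemble rules and model accounting."""

import numpy as np
import pytest

from taxoclass import (
    SimulationConfig,
    TaxonomyShape,
    evolve_genomes,
    simulate_reads,
    synth_taxonomy,
)
from taxoclass.classify import KmerProfileModel, Prediction
from taxoclass.errors import EmptyAllowedError, MissingModelError
from taxoclass.hierarchy import (
    StrategySpec,
    assemble,
    count_models,
    ensemble_primary_align,
    ensemble_primary_specialist,
    ensemble_union,
    headline,
    predict_hi_lcl,
    predict_lcl,
    predict_lcl_lcpn,
    predict_lcpn,
    train_components,
)
from taxoclass.taxonomy import SUB_ROOT_RANKS


class Stub:
    """Deterministic classifier stub: fixed per-label weights, softmax by
    renormalization over the allowed subset."""

    def __init__(self, weights: dict[int, float]):
        self.weights = weights
        self.labels = sorted(weights)

    def predict(self, read_pair, allowed=None):
        labs = self.labels if allowed is None else [
            l for l in self.labels if l in allowed
        ]
        if not labs:
            raise EmptyAllowedError("no stub labels allowed")
        total = sum(self.weights[l] for l in labs)
        best = max(labs, key=lambda l: (self.weights[l], -l))
        return best, self.weights[best] / total, {
            l: self.weights[l] for l in labs
        }


@pytest.fixture(scope="module")
def tax():
    # 2 phyla -> ... -> 2 genera/family -> 3 species/genus (12 species)
    return synth_taxonomy(TaxonomyShape(2, 1, 1, 1, 2, 3))


def rank_stubs(t, weights_by_rank):
    return {rank: Stub(weights_by_rank[rank]) for rank in SUB_ROOT_RANKS}


def uniform_rank_stubs(t, chosen: int):
    """Stubs that confidently follow the lineage of ``chosen`` at each rank."""
    out = {}
    for rank in SUB_ROOT_RANKS:
        taxa = t.taxa_at_rank(rank)
        target = t.project(chosen, rank)
        out[rank] = Stub({x: (0.9 if x == target else 0.1 / (len(taxa) - 1))
                          for x in taxa})
    return out


class TestAssemble:
    def test_lcl_with_six_rank_models_is_valid(self, tax):
        sp = tax.taxa_at_rank("species")[0]
        spec = StrategySpec("lcl")
        m = assemble(spec, {"rank_models": uniform_rank_stubs(tax, sp)}, tax)
        assert set(m.rank_models) == set(SUB_ROOT_RANKS)

    def test_lcpn_missing_genus_model_is_named(self, tax):
        spec = StrategySpec("lcpn")
        sp = tax.taxa_at_rank("species")[0]
        comp = train_stub_nodes(tax)
        victim = tax.taxa_at_rank("genus")[0]
        del comp["node_models"][victim]
        with pytest.raises(MissingModelError, match=str(victim)):
            assemble(spec, comp, tax)

    def test_lcl_lcpn_requires_upper_ranks_and_lower_nodes(self, tax):
        spec = StrategySpec("lcl_lcpn")
        sp = tax.taxa_at_rank("species")[0]
        rank_models = {
            r: uniform_rank_stubs(tax, sp)[r]
            for r in ("phylum", "class", "order", "family")
        }
        node_models = {
            parent: Stub({kid: 1.0 for kid in tax.children_of(parent)})
            for parent in tax.taxa_at_rank("family") + tax.taxa_at_rank("genus")
        }
        m = assemble(spec, {"rank_models": rank_models,
                            "node_models": node_models}, tax)
        assert len(m.node_models) == 6  # 2 families + 4 genera

    def test_node_model_label_mismatch_rejected(self, tax):
        spec = StrategySpec("lcpn")
        comp = train_stub_nodes(tax)
        genus = tax.taxa_at_rank("genus")[0]
        comp["node_models"][genus] = Stub({1: 1.0})  # wrong labels
        with pytest.raises(MissingModelError, match="labels"):
            assemble(spec, comp, tax)


def train_stub_nodes(t):
    node_models = {}
    for rank in ["root", "phylum", "class", "order", "family", "genus"]:
        nodes = [t.root] if rank == "root" else t.taxa_at_rank(rank)
        for node in nodes:
            kids = t.children_of(node)
            if len(kids) > 1:
                node_models[node] = Stub({k: 1.0 for k in kids})
    return {"node_models": node_models}


class TestLcl:
    def test_confident_models_give_species_headline(self, tax):
        sp = tax.taxa_at_rank("species")[0]
        m = assemble(StrategySpec("lcl"),
                     {"rank_models": uniform_rank_stubs(tax, sp)}, tax)
        out = predict_lcl(m, ("ACGT", None))
        assert len(out) == 6
        assert headline(out).taxon == sp and headline(out).rank == "species"

    def test_low_species_confidence_drops_to_genus(self, tax):
        sp = tax.taxa_at_rank("species")[0]
        stubs = uniform_rank_stubs(tax, sp)
        species_taxa = tax.taxa_at_rank("species")
        # argmax species keeps only 0.4 of the mass
        stubs["species"] = Stub(
            {x: (0.4 if x == sp else 0.6 / (len(species_taxa) - 1))
             for x in species_taxa}
        )
        m = assemble(StrategySpec("lcl"), {"rank_models": stubs}, tax)
        out = predict_lcl(m, ("ACGT", None))
        assert out["species"].is_unclassified
        assert headline(out).rank == "genus"

    def test_symmetric_models_all_unclassified(self):
        # needs >= 3 candidates per rank so the flat softmax 1/K < 0.5
        t3 = synth_taxonomy(TaxonomyShape(3, 1, 1, 1, 2, 3))
        stubs = {
            rank: Stub({x: 1.0 for x in t3.taxa_at_rank(rank)})
            for rank in SUB_ROOT_RANKS
        }
        m = assemble(StrategySpec("lcl"), {"rank_models": stubs}, t3)
        out = predict_lcl(m, ("ACGT", None))
        assert all(p.is_unclassified for p in out.values())


class TestHiLcl:
    def test_restriction_follows_parent_prediction(self, tax):
        p1, p2 = tax.taxa_at_rank("phylum")
        c1 = tax.children_of(p1)[0]
        c2 = tax.children_of(p2)[0]
        stubs = uniform_rank_stubs(tax, tax.children_at(p1, "species").pop())
        # phylum model says p1, but the unrestricted class argmax is in p2
        stubs["phylum"] = Stub({p1: 0.9, p2: 0.1})
        stubs["class"] = Stub({c1: 0.2, c2: 0.8})
        m = assemble(StrategySpec("hi_lcl"), {"rank_models": stubs}, tax)
        path = predict_hi_lcl(m, ("ACGT", None))
        assert path[0].taxon == p1
        # restricted to p1's single class -> that class with softmax 1
        assert path[1].taxon == c1 and path[1].confidence == pytest.approx(1.0)

    def test_phylum_below_threshold_gives_empty_path(self):
        t3 = synth_taxonomy(TaxonomyShape(3, 1, 1, 1, 2, 3))
        stubs = {rank: Stub({x: 1.0 for x in t3.taxa_at_rank(rank)})
                 for rank in SUB_ROOT_RANKS}
        m = assemble(StrategySpec("hi_lcl"), {"rank_models": stubs}, t3)
        assert predict_hi_lcl(m, ("ACGT", None)) == []

    def test_paths_are_ancestor_consistent(self, tax):
        sp = tax.taxa_at_rank("species")[-1]
        m = assemble(StrategySpec("hi_lcl"),
                     {"rank_models": uniform_rank_stubs(tax, sp)}, tax)
        path = predict_hi_lcl(m, ("ACGT", None))
        for parent, child in zip(path, path[1:]):
            assert tax.parent_of(child.taxon) == parent.taxon


class TestLcpn:
    def test_confident_path_reaches_species(self, tax):
        comp = train_stub_nodes(tax)
        # bias every node model toward the first child
        for node, stub in comp["node_models"].items():
            kids = sorted(stub.weights)
            stub.weights = {k: (0.8 if k == kids[0] else 0.2 / (len(kids) - 1))
                            for k in kids}
        m = assemble(StrategySpec("lcpn"), comp, tax)
        path = predict_lcpn(m, ("ACGT", None))
        assert [p.rank for p in path] == list(SUB_ROOT_RANKS)
        for parent, child in zip(path, path[1:]):
            assert tax.parent_of(child.taxon) == parent.taxon

    def test_weak_species_stage_stops_at_genus(self, tax):
        comp = train_stub_nodes(tax)
        m = assemble(StrategySpec("lcpn"), comp, tax)
        genus = None
        for node, stub in m.node_models.items():
            if tax.rank_of(node) == "genus":
                kids = sorted(stub.weights)
                stub.weights = {k: 1.0 for k in kids}  # 1/3 < 0.5
        path = predict_lcpn(m, ("ACGT", None))
        assert path[-1].rank == "genus"

    def test_wrong_phylum_choice_compounds(self, tax):
        # a read from phylum A routed into phylum B stays in B's subtree
        p1, p2 = tax.taxa_at_rank("phylum")
        comp = train_stub_nodes(tax)
        comp["node_models"][tax.root] = Stub({p1: 0.1, p2: 0.9})
        m = assemble(StrategySpec("lcpn"), comp, tax)
        path = predict_lcpn(m, ("ACGT", None))
        assert path[0].taxon == p2
        assert all(tax.project(p.taxon, "phylum") == p2 for p in path)


class TestLclLcpn:
    def _components(self, tax, sp):
        rank_models = {
            r: uniform_rank_stubs(tax, sp)[r]
            for r in ("phylum", "class", "order", "family")
        }
        node_models = {
            parent: Stub({kid: (0.9 if tax.project(sp, tax.rank_of(kid))
                                == kid else 0.1)
                          for kid in tax.children_of(parent)})
            for parent in tax.taxa_at_rank("family") + tax.taxa_at_rank("genus")
        }
        return {"rank_models": rank_models, "node_models": node_models}

    def test_full_confidence_reaches_species(self, tax):
        sp = tax.taxa_at_rank("species")[0]
        m = assemble(StrategySpec("lcl_lcpn"), self._components(tax, sp), tax)
        path = predict_lcl_lcpn(m, ("ACGT", None))
        assert path[-1].taxon == sp and path[-1].rank == "species"
        for parent, child in zip(path, path[1:]):
            assert tax.parent_of(child.taxon) == parent.taxon

    def test_unclassified_family_stops_descent(self, tax):
        sp = tax.taxa_at_rank("species")[0]
        comp = self._components(tax, sp)
        fams = tax.taxa_at_rank("family")
        comp["rank_models"]["family"] = Stub({f: 1.0 for f in fams})
        # two families tie at softmax 0.5; a 0.6 threshold leaves the
        # family rank unclassified so no node model ever runs
        m = assemble(StrategySpec("lcl_lcpn", threshold=0.6), comp, tax)
        path = predict_lcl_lcpn(m, ("ACGT", None))
        assert path[-1].rank == "order"

    def test_weak_genus_stage_stops_at_family(self, tax):
        sp = tax.taxa_at_rank("species")[0]
        comp = self._components(tax, sp)
        family = tax.project(sp, "family")
        kids = tax.children_of(family)
        comp["node_models"][family] = Stub(
            {k: (0.3 if k == tax.project(sp, "genus") else 0.7) for k in kids}
        )
        # make the 0.7-weight genus lose so argmax softmax is 0.7 > 0.5?
        # no: use equal weights so softmax = 0.5 exactly at 2 kids; force 0.3
        comp["node_models"][family] = Stub({k: 1.0 for k in kids})
        m = assemble(StrategySpec("lcl_lcpn"),
                     {**comp}, tax)
        m.spec = StrategySpec("lcl_lcpn", threshold=0.6)
        path = predict_lcl_lcpn(m, ("ACGT", None))
        assert path[-1].rank == "family"


@pytest.fixture(scope="module")
def ensemble_setup(tax):
    genus = tax.taxa_at_rank("genus")[0]
    s1, s2, s3 = tax.children_of(genus)
    spec = StrategySpec("primary_specialist")
    return tax, genus, (s1, s2, s3), spec


class TestEnsembleRules:
    def test_confident_specialist_overrides(self, ensemble_setup):
        tax, genus, (s1, s2, s3), spec = ensemble_setup
        m = assemble_specialists(tax, spec, {s1: 0.6, s2: 0.3, s3: 0.1})
        primary = Prediction("r", genus, "genus", None, "primary")
        out = ensemble_primary_specialist(primary, m, ("ACGT", None))
        assert out.taxon == s1 and out.rank == "species"
        assert out.source == "specialist"

    def test_weak_specialist_falls_back_to_primary(self, ensemble_setup):
        tax, genus, (s1, s2, s3), spec = ensemble_setup
        m = assemble_specialists(tax, spec, {s1: 0.4, s2: 0.3, s3: 0.3})
        primary = Prediction("r", genus, "genus", None, "primary")
        out = ensemble_primary_specialist(primary, m, ("ACGT", None))
        assert out == primary

    def test_unclassified_primary_stays_unclassified(self, ensemble_setup):
        tax, genus, _, spec = ensemble_setup
        m = assemble_specialists(tax, spec, None)
        primary = Prediction.unclassified("r", "primary")
        out = ensemble_primary_specialist(primary, m, ("ACGT", None))
        assert out.is_unclassified

    def test_primary_above_genus_passes_through(self, ensemble_setup):
        tax, genus, _, spec = ensemble_setup
        m = assemble_specialists(tax, spec, None)
        family = tax.taxa_at_rank("family")[0]
        primary = Prediction("r", family, "family", None, "primary")
        assert ensemble_primary_specialist(primary, m, ("A", None)) == primary

    def test_threshold_one_returns_primary_everywhere(self, tax):
        # fallback totality: nothing the specialist says can displace the
        # primary when the acceptance bar is unreachable
        genus = tax.taxa_at_rank("genus")[0]
        s1, s2, s3 = tax.children_of(genus)
        spec = StrategySpec("primary_specialist", threshold=1.0)
        m = assemble_specialists(tax, spec, {s1: 0.97, s2: 0.02, s3: 0.01})
        for primary in (
            Prediction("r", genus, "genus", None, "primary"),
            Prediction("r", s2, "species", None, "primary"),
            Prediction.unclassified("r", "primary"),
        ):
            assert ensemble_primary_specialist(primary, m, ("A", None)) == primary

    def test_align_unique_best_species_wins(self, tax):
        from taxoclass.classify import AlignIndex

        genus = tax.taxa_at_rank("genus")[0]
        s1, s2, _ = tax.children_of(genus)
        rng = np.random.default_rng(40)
        ref1 = "".join(rng.choice(list("ACGT"), size=500))
        ref2 = "".join(rng.choice(list("ACGT"), size=500))
        spec = StrategySpec("primary_align")
        m = assemble(spec, {
            "primary": object(),
            "specialists": {
                g: AlignIndex({s: [("r", ref1 if s == s1 else ref2)]
                               for s in tax.children_of(g)})
                for g in tax.taxa_at_rank("genus")
            },
        }, tax)
        primary = Prediction("r", genus, "genus", None, "primary")
        out = ensemble_primary_align(primary, m, (ref1[100:250], None))
        assert out.taxon == s1 and out.rank == "species"

    def test_align_tie_falls_back(self, tax):
        from taxoclass.classify import AlignIndex

        genus = tax.taxa_at_rank("genus")[0]
        rng = np.random.default_rng(41)
        shared = "".join(rng.choice(list("ACGT"), size=500))
        spec = StrategySpec("primary_align")
        m = assemble(spec, {
            "primary": object(),
            "specialists": {
                g: AlignIndex({s: [("r", shared)]
                               for s in tax.children_of(g)})
                for g in tax.taxa_at_rank("genus")
            },
        }, tax)
        primary = Prediction("r", genus, "genus", None, "primary")
        assert ensemble_primary_align(primary, m, (shared[:150], None)) == primary

    def test_align_primary_at_family_passes_through(self, tax):
        spec = StrategySpec("primary_align")
        m = assemble_specialists(tax, spec, None)
        family = tax.taxa_at_rank("family")[0]
        primary = Prediction("r", family, "family", None, "primary")
        assert ensemble_primary_align(primary, m, ("A", None)) == primary

    def test_union_precedence(self, tax):
        s_taxa = tax.taxa_at_rank("species")
        genus = tax.taxa_at_rank("genus")[0]
        sp1 = Prediction("r", s_taxa[0], "species", None, "a")
        sp2 = Prediction("r", s_taxa[1], "species", None, "b")
        gen = Prediction("r", genus, "genus", None, "a")
        gen2 = Prediction("r", genus, "genus", None, "b")
        assert ensemble_union(sp1, sp2, tax) == sp1
        assert ensemble_union(gen, sp2, tax) == sp2
        assert ensemble_union(gen, gen2, tax) == gen


def assemble_specialists(tax, spec, first_genus_weights):
    specialists = {}
    for g in tax.taxa_at_rank("genus"):
        kids = tax.children_of(g)
        if first_genus_weights and g == tax.taxa_at_rank("genus")[0]:
            specialists[g] = Stub(first_genus_weights)
        else:
            specialists[g] = Stub({k: 1.0 for k in kids})
    return assemble(spec, {"primary": object(), "specialists": specialists},
                    tax)


class TestCountModels:
    def test_lcl_is_six(self, tax):
        assert count_models(StrategySpec("lcl"), tax) == 6
        assert count_models(StrategySpec("hi_lcl"), tax) == 6

    def test_flat_is_one(self, tax):
        assert count_models(StrategySpec("flat"), tax) == 1

    def test_lcpn_multichild_counts_branching_parents(self):
        # root has 2 phyla; one phylum has 2 classes; everything else chains
        records = [
            (1, 1, "root", "r"),
            (2, 1, "phylum", "pA"), (3, 1, "phylum", "pB"),
            (4, 2, "class", "cA1"), (5, 2, "class", "cA2"),
            (6, 3, "class", "cB"),
        ]
        nid = 7
        for cls in (4, 5, 6):
            parent = cls
            for rank in ("order", "family", "genus", "species"):
                records.append((nid, parent, rank, f"{rank}{nid}"))
                parent = nid
                nid += 1
        from taxoclass import build_taxonomy

        t = build_taxonomy(records)
        assert count_models(
            StrategySpec("lcpn", model_policy="multichild_only"), t
        ) == 2
        assert count_models(
            StrategySpec("lcpn", model_policy="all_parents"), t
        ) == 1 + 2 + 3 + 3 + 3 + 3

    def test_toy_counts_are_consistent(self, tax):
        # (2,1,1,1,2,3): branching at root, families and genera
        assert count_models(StrategySpec("lcpn"), tax) == 1 + 2 + 4
        assert count_models(StrategySpec("lcl_lcpn"), tax) == 4 + 2 + 4
        assert count_models(StrategySpec("primary_specialist"), tax) == 1 + 4


class TestDegenerateEquivalence:
    def test_single_candidate_everywhere_all_strategies_agree(self):
        t = synth_taxonomy(TaxonomyShape(1, 1, 1, 1, 1, 1))
        sp = t.taxa_at_rank("species")[0]
        rank_models = {
            rank: KmerProfileModel.single_label(t.taxa_at_rank(rank)[0])
            for rank in SUB_ROOT_RANKS
        }
        read = ("ACGTACGTACGTACGT", None)
        lcl_m = assemble(StrategySpec("lcl"), {"rank_models": rank_models}, t)
        hi_m = assemble(StrategySpec("hi_lcl"), {"rank_models": rank_models}, t)
        lcpn_m = assemble(StrategySpec("lcpn"), {}, t)
        hyb_m = assemble(StrategySpec("lcl_lcpn"), {
            "rank_models": {r: rank_models[r]
                            for r in ("phylum", "class", "order", "family")},
        }, t)
        results = [
            headline(predict_lcl(lcl_m, read)).taxon,
            predict_hi_lcl(hi_m, read)[-1].taxon,
            predict_lcpn(lcpn_m, read)[-1].taxon,
            predict_lcl_lcpn(hyb_m, read)[-1].taxon,
        ]
        assert results == [sp] * 4


class TestTrainedStrategiesOnCommunity:
    def test_paths_ancestor_consistent_on_simulated_reads(self):
        cfg = SimulationConfig(shape=TaxonomyShape(2, 1, 1, 1, 2, 2),
                               genome_len=8000, reads_per_species=20,
                               seed=5)
        t = synth_taxonomy(cfg.shape, 5)
        com = evolve_genomes(t, cfg)
        train = simulate_reads(com.train_assemblies, cfg, stage="train")
        by_sp = {}
        for pair, sp in train:
            by_sp.setdefault(sp, []).append(pair)
        test = simulate_reads(com.test_assemblies, cfg, stage="test")[:40]
        for strategy, fn in (("hi_lcl", predict_hi_lcl),
                             ("lcpn", predict_lcpn),
                             ("lcl_lcpn", predict_lcl_lcpn)):
            spec = StrategySpec(strategy)
            comp = train_components(by_sp, t, spec, seed=5)
            m = assemble(spec, comp, t)
            for pair, sp in test:
                path = fn(m, pair)
                for parent, child in zip(path, path[1:]):
                    assert t.parent_of(child.taxon) == parent.taxon
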