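"""Hypergeometric tails against exhaustive enumeration; gene/TFBS set machinery."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st

from longewas.core_io import EnrichmentQuery, ValidationError
from longewas.enrichment import (
    GeneSetCollection,
    annotate_cpgs_to_genes,
    enrich_gene_list,
    hypergeometric_enrichment,
    read_gmt,
    tfbs_enrichment,
    write_gmt,
)


def enumerate_tail(n, m, r, k):
    """Exhaustive oracle: fraction of all C(n, r) draws with overlap >= k."""
    universe = range(n)
    special = set(range(m))
    hits = sum(1 for draw in itertools.combinations(universe, r)
               if len(special.intersection(draw)) >= k)
    return hits / comb(n, r)


class TestHypergeometricTail:
    def test_worked_example(self):
        q = EnrichmentQuery(universe_size=10, set_size=4, marker_size=3, overlap=3)
        assert hypergeometric_enrichment(q) == pytest.approx(4 / 120)

    def test_k_zero_is_one(self):
        q = EnrichmentQuery(universe_size=10, set_size=4, marker_size=3, overlap=0)
        assert hypergeometric_enrichment(q) == pytest.approx(1.0)

    def test_printed_formula_excludes_observed_overlap(self):
        q = EnrichmentQuery(universe_size=10, set_size=4, marker_size=3, overlap=3)
        assert hypergeometric_enrichment(q, tail="paper_gt") == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [4, 7, 9])
    def test_matches_enumeration(self, n):
        for m in range(n + 1):
            for r in range(n + 1):
                for k in range(min(m, r) + 1):
                    q = EnrichmentQuery(n, m, r, k)
                    assert hypergeometric_enrichment(q) == pytest.approx(
                        enumerate_tail(n, m, r, k), abs=1e-12)

    @given(st.integers(1, 40).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n), st.integers(0, n))))
    def test_tail_conventions_relation(self, nmr):
        n, m, r = nmr
        for k in range(1, min(m, r) + 1):
            geq = hypergeometric_enrichment(EnrichmentQuery(n, m, r, k))
            gt_prev = hypergeometric_enrichment(EnrichmentQuery(n, m, r, k - 1), tail="paper_gt")
            assert geq == pytest.approx(gt_prev, abs=1e-12)

    def test_query_invariants(self):
        with pytest.raises(ValidationError):
            EnrichmentQuery(10, 11, 3, 0)
        with pytest.raises(ValidationError):
            EnrichmentQuery(10, 4, 3, 4)


class TestAnnotation:
    def test_manifest_lookup(self, tiny_manifest):
        assert annotate_cpgs_to_genes(["cg14671384"], tiny_manifest) == ["SLC38A4"]

    def test_empty_gene_excluded_and_deduplication(self, tiny_manifest):
        genes = annotate_cpgs_to_genes(
            ["cg14671384", "cgSAMEGENE1", "cgAUTOSOMAL"], tiny_manifest)
        assert genes == ["SLC38A4"]

    def test_multi_gene_annotations_split(self, tiny_manifest):
        genes = annotate_cpgs_to_genes(["cg02539153"], tiny_manifest)
        assert genes == ["CH17-40K24.2", "PCDHB18"]

    def test_unknown_probe_errors(self, tiny_manifest):
        with pytest.raises(ValidationError, match="cgNOPE"):
            annotate_cpgs_to_genes(["cgNOPE"], tiny_manifest)


def _collection(universe_n=40, n_sets=4, set_size=8, seed=0):
    rng = np.random.default_rng(seed)
    universe = [f"G{i:03d}" for i in range(universe_n)]
    sets = {f"SET{i}": (f"desc {i}", frozenset(rng.choice(universe, set_size, replace=False)))
            for i in range(n_sets)}
    return GeneSetCollection(sets=sets, universe=frozenset(universe)), universe


class TestEnrichGeneList:
    def test_whole_set_ranks_first_with_minimal_p(self):
        coll, universe = _collection()
        target = sorted(coll.sets["SET2"][1])
        table = enrich_gene_list(target, coll)
        assert table.iloc[0]["set_id"] == "SET2"
        n, r = len(universe), len(target)
        assert table.iloc[0]["p_value"] == pytest.approx(1 / comb(n, r), rel=1e-9)

    def test_disjoint_genes_give_p_one(self):
        coll, universe = _collection()
        members = set().union(*(m for _, m in coll.sets.values()))
        outside = sorted(set(universe) - members)[:5]
        table = enrich_gene_list(outside, coll)
        assert (table["p_value"] == 1.0).all()

    def test_growing_universe_strictly_decreases_p(self):
        # fixed M, R, k while N doubles: over-representation strengthens
        for n in (20, 40, 80, 160):
            pa = hypergeometric_enrichment(EnrichmentQuery(n, 6, 5, 3))
            pb = hypergeometric_enrichment(EnrichmentQuery(2 * n, 6, 5, 3))
            assert pb < pa

    def test_universe_required(self):
        sets = {"S": ("d", frozenset(["a", "b"]))}
        coll = GeneSetCollection(sets=sets)
        with pytest.raises(ValidationError, match="universe"):
            enrich_gene_list(["a"], coll)
        table = enrich_gene_list(["a"], coll, universe_size_override=100)
        assert table.iloc[0]["N"] == 100

    def test_set_member_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside the universe"):
            GeneSetCollection(sets={"S": ("d", frozenset(["a", "zzz"]))},
                              universe=frozenset(["a", "b"]))


class TestGmt:
    def test_round_trip(self, tmp_path):
        coll, _ = _collection()
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert {k: v[1] for k, v in back.sets.items()} == {k: v[1] for k, v in coll.sets.items()}

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ONLY_ID\tdesc\n")
        with pytest.raises(ValidationError, match="malformed"):
            read_gmt(path)


class TestTfbs:
    def test_perfectly_specific_tf_attains_minimal_p(self):
        universe = [f"cg{i}" for i in range(30)]
        selected = universe[:5]
        annot = {p: (["TFA"] if p in selected else ["TFB"]) for p in universe}
        table = tfbs_enrichment(selected, annot).set_index("tf")
        assert table.loc["TFA", "p_value"] == pytest.approx(1 / comb(30, 5), rel=1e-9)
        assert table.loc["TFB", "p_value"] == pytest.approx(1.0)

    def test_selection_equal_to_universe_forces_p_one(self):
        universe = [f"cg{i}" for i in range(12)]
        annot = {p: ["TFA"] if int(p[2:]) % 2 else [] for p in universe}
        table = tfbs_enrichment(universe, annot)
        assert (table["p_value"] == 1.0).all()

    def test_probe_outside_annotation_errors(self):
        with pytest.raises(ValidationError, match="missing from"):
            tfbs_enrichment(["cgX"], {"cgA": ["TFA"]})
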