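"""Hypergeometric tails, BH correction, cluster-composition and pathway tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gcrep import (
    bh_adjust,
    categorical_enrichment_by_cluster,
    composition_table,
    hypergeom_lower_tail,
    hypergeom_upper_tail,
    pathway_enrichment,
)
from gcrep.io import GeneSetCollection

from test_clonotypes import make_cell


def exact_upper_tail(k, K, n, N):
    """Independent combinatorial oracle: exact big-integer tail sum."""
    num = sum(math.comb(K, x) * math.comb(N - K, n - x)
              for x in range(max(k, 0, n - (N - K)), min(n, K) + 1))
    return num / math.comb(N, n)


def exact_lower_tail(k, K, n, N):
    num = sum(math.comb(K, x) * math.comb(N - K, n - x)
              for x in range(max(0, n - (N - K)), min(k, n, K) + 1))
    return num / math.comb(N, n)


class TestHypergeomTails:
    def test_certain_and_impossible_events(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0
        assert hypergeom_upper_tail(5, 5, 4, 10) == 0.0  # k > min(n, K)
        assert hypergeom_lower_tail(4, 5, 4, 10) == 1.0  # k = min(n, K)
        assert hypergeom_lower_tail(0, 8, 8, 10) == 0.0  # below support

    def test_worked_upper_tail(self):
        # C(5,3)C(5,1)+C(5,4)C(5,0) over C(10,4) = (50+5)/210
        assert hypergeom_upper_tail(3, 5, 4, 10) == pytest.approx(
            55 / 210, rel=1e-12
        )
        assert exact_upper_tail(3, 5, 4, 10) == pytest.approx(55 / 210, rel=0)

    def test_worked_lower_tail(self):
        # C(5,0)C(5,4)+C(5,1)C(5,3) over C(10,4) = (5+50)/210
        assert hypergeom_lower_tail(1, 5, 4, 10) == pytest.approx(
            55 / 210, rel=1e-12
        )

    @given(
        st.integers(1, 80).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            )
        )
    )
    def test_tails_complementary_and_match_oracle(self, params):
        N, K, n = params
        for k in range(0, min(n, K) + 1):
            up = hypergeom_upper_tail(k, K, n, N)
            lo = hypergeom_lower_tail(k - 1, K, n, N) if k > 0 else 0.0
            assert up + lo == pytest.approx(1.0, rel=1e-10)
            assert up == pytest.approx(exact_upper_tail(k, K, n, N), rel=1e-11)

    def test_vectorized_k_matches_scalar(self):
        ks = np.arange(0, 9)
        vec = hypergeom_upper_tail(ks, 20, 8, 100)
        for k, v in zip(ks, vec):
            assert v == hypergeom_upper_tail(int(k), 20, 8, 100)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_lower_tail(-1, 5, 4, 10)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p[perm]), q[perm])
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _composition_cells(counts_by_cluster):
    """counts_by_cluster: {cluster: {subclass: count}}"""
    cells = []
    i = 0
    for cluster, comp in counts_by_cluster.items():
        for subclass, count in comp.items():
            for _ in range(count):
                cell = make_cell(f"bc{i}", cdr3_h="TGT" + "AAA" * (i + 1),
                                 subclass=subclass)
                cell.cluster = cluster
                cells.append(cell)
                i += 1
    return cells


class TestCategoricalEnrichment:
    def test_null_composition_has_no_flags(self):
        comp = {"IGHM": 20, "IGHG1": 20, "IGHA1": 20}
        cells = _composition_cells({"DZ-1": comp, "LZ-1": comp, "PreM": comp})
        records = categorical_enrichment_by_cluster(cells, "isotype_class")
        assert all(r.flag == "none" for r in records)

    def test_extreme_cluster_flagged_both_ways(self):
        cells = _composition_cells(
            {
                "DZ-1": {"IGHM": 100},
                "LZ-1": {"IGHM": 300, "IGHG1": 300, "IGHA1": 300},
            }
        )
        records = categorical_enrichment_by_cluster(cells, "isotype_class")
        by = {(r.cluster, r.category): r for r in records}
        assert by[("DZ-1", "IGHM")].flag == "enriched"
        assert by[("DZ-1", "IGHG")].flag == "depleted"
        assert by[("DZ-1", "IGHA")].flag == "depleted"
        # p-values agree with the combinatorial oracle
        r = by[("DZ-1", "IGHM")]
        assert r.p_enrich == pytest.approx(
            exact_upper_tail(r.k, r.K, r.n, r.N), rel=1e-10
        )

    def test_never_enriched_and_depleted_simultaneously(self):
        cells = _composition_cells(
            {
                "DZ-1": {"IGHM": 50, "IGHG1": 10},
                "LZ-1": {"IGHM": 10, "IGHG1": 50},
                "PBL-1": {"IGHG1": 60},
            }
        )
        records = categorical_enrichment_by_cluster(cells, "isotype_class")
        for r in records:
            assert not (r.q_enrich <= 0.05 and r.q_deplete <= 0.05)
            assert r.p_enrich + r.p_deplete >= 1.0 - 1e-12  # shared point mass

    def test_composition_rows_sum_to_100(self):
        cells = _composition_cells(
            {"DZ-1": {"IGHM": 7, "IGHG2": 5}, "LZ-2": {"IGHA2": 3}}
        )
        table = composition_table(cells, "isotype_class")
        sums = table[["IGHM", "IGHG", "IGHA", "IGHE"]].sum(axis=1)
        assert np.allclose(sums, 100.0)


class TestPathwayEnrichment:
    def _collection(self):
        return GeneSetCollection(
            sets={
                "TARGET": [f"G{i}" for i in range(10)],
                "OTHER": [f"G{i}" for i in range(40, 55)],
                "DISJOINT": [f"G{i}" for i in range(70, 80)],
            }
        )

    def test_signature_equal_to_set_ranks_first(self):
        universe = [f"G{i}" for i in range(100)]
        table = pathway_enrichment([f"G{i}" for i in range(10)],
                                   self._collection(), universe)
        assert table.iloc[0]["set"] == "TARGET"
        assert table.iloc[0]["p_value"] < table.iloc[-1]["p_value"]

    def test_zero_overlap_has_p_exactly_one(self):
        universe = [f"G{i}" for i in range(100)]
        table = pathway_enrichment([f"G{i}" for i in range(10)],
                                   self._collection(), universe)
        row = table[table["set"] == "DISJOINT"].iloc[0]
        assert row["overlap"] == 0
        assert row["p_value"] == 1.0

    def test_overlap_five_matches_combinatorial_oracle(self):
        universe = [f"G{i}" for i in range(100)]
        signature = [f"G{i}" for i in range(5)] + [f"G{i}" for i in range(90, 95)]
        table = pathway_enrichment(signature, self._collection(), universe)
        row = table[table["set"] == "TARGET"].iloc[0]
        assert row["overlap"] == 5
        assert row["p_value"] == pytest.approx(
            exact_upper_tail(5, 10, 10, 100), rel=1e-10
        )

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment(["A"], self._collection(), [])
        with pytest.raises(ValueError):
            pathway_enrichment(["NOT_IN_UNIVERSE"], self._collection(), ["G1"])
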