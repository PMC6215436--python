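"""Enrichment statistics: p-value, ratio, FDR, normalized D."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmienrich import (
    DMIStrategy,
    ShuffleConfig,
    StrategyMode,
    UndefinedStatError,
    dmi_fdr,
    empirical_pvalue,
    enrichment_ratio,
    format_sigfig,
    normalized_D,
    run_enrichment,
)


class TestEmpiricalPValue:
    def test_zero_exceedances_displayed_as_bound(self):
        r = np.arange(1000) % 14  # all < 14
        p = empirical_pvalue(14, r)
        assert p.value == 0.0
        assert p.display == "<0.001"

    def test_all_ties_give_one(self):
        p = empirical_pvalue(5, [5, 5, 5, 5])
        assert p.value == 1.0

    def test_partial(self):
        p = empirical_pvalue(3, [0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        assert p.value == pytest.approx(0.7)

    def test_empty_distribution_rejected(self):
        with pytest.raises(UndefinedStatError):
            empirical_pvalue(1, [])

    @given(o=st.integers(0, 20), r=st.lists(st.integers(0, 20), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_monotonicity_in_observed(self, o, r):
        p = empirical_pvalue(o, r).value
        assert 0.0 <= p <= 1.0
        assert empirical_pvalue(o + 1, r).value <= p
        assert dmi_fdr(o + 1, float(np.mean(r))) <= dmi_fdr(o, float(np.mean(r))) or o == 0


class TestEnrichmentRatio:
    def test_no_enrichment_is_one(self):
        assert enrichment_ratio(5, 5.0) == 1.0

    def test_zero_mean_is_infinite_sentinel(self):
        assert math.isinf(enrichment_ratio(3, 0.0))
        assert math.isnan(enrichment_ratio(0, 0.0))


class TestFdr:
    def test_cap_rule(self):
        assert dmi_fdr(10, 25.0) == 1.0

    def test_zero_observed(self):
        assert dmi_fdr(0, 3.0) == 0.0

    @given(o=st.integers(1, 1000), rbar=st.floats(0, 2000, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_in_unit_interval(self, o, rbar):
        assert 0.0 <= dmi_fdr(o, rbar) <= 1.0


class TestNormalizedD:
    def test_direct_substitution(self):
        assert normalized_D(10, [5, 5]).tolist() == [1.0, 1.0]
        np.testing.assert_allclose(normalized_D(0, [2, 4]), [-2 / 3, -4 / 3])

    def test_undefined_when_mean_zero(self):
        with pytest.raises(UndefinedStatError):
            normalized_D(3, [0, 0])

    @given(
        o=st.integers(0, 50),
        r=st.lists(st.integers(0, 50), min_size=2, max_size=40).filter(lambda x: sum(x) > 0),
    )
    @settings(max_examples=150, deadline=None)
    def test_enrichment_is_one_plus_mean_d(self, o, r):
        d = normalized_D(o, r)
        enr = enrichment_ratio(o, float(np.mean(r)))
        assert enr == pytest.approx(1.0 + float(d.mean()), abs=1e-9)


# printed headline values: (observed, mean_random, enrichment_3sf, fdr_4dp)
HEADLINE_ROWS = [
    (14, 0.122, "115", "0.0087"),
    (25, 0.830, "30.1", "0.0332"),
    (74, 9.76, "7.58", "0.1319"),
    (204, 139, "1.47", None),
    (1524, 1310, "1.16", None),
]


@pytest.mark.parametrize("o,rbar,enr,fdr", HEADLINE_ROWS)
def test_headline_internal_consistency(o, rbar, enr, fdr):
    assert format_sigfig(enrichment_ratio(o, rbar), 3) == enr
    if fdr is not None:
        assert f"{dmi_fdr(o, rbar):.4f}" == fdr


class TestRunEnrichment:
    def test_degenerate_empty_potential(self, toy):
        from dmienrich import DMIDefinitionTable

        empty_defs = DMIDefinitionTable(schema_kind="protein-protein", rows=[])
        res = run_enrichment(
            toy["ppi"], None, empty_defs, None,
            DMIStrategy(StrategyMode.ELMI_PROTEIN),
            ShuffleConfig(n_shuffles=25, seed=0))
        assert res.observed == 0
        assert res.p_value.value == 1.0  # every R_i = 0 >= 0
        assert res.fdr == 0.0
        assert res.D is None

    def test_deterministic_given_seed(self, toy):
        cfg = ShuffleConfig(n_shuffles=40, seed=5)
        strat = DMIStrategy(StrategyMode.ELMC_DOMAIN)
        r1 = run_enrichment(toy["ppi"], toy["motifs_known"], toy["dmi_motif_domain"],
                            toy["domains"], strat, cfg)
        r2 = run_enrichment(toy["ppi"], toy["motifs_known"], toy["dmi_motif_domain"],
                            toy["domains"], strat, cfg)
        assert r1.random.counts.tolist() == r2.random.counts.tolist()
        # realized pairs: (K1,Q1) and (K2,Q2), one annotation route each
        assert r1.observed == r2.observed == 2

    def test_toy_statistics_consistent(self, toy):
        strat = DMIStrategy(StrategyMode.ELMC_DOMAIN)
        res = run_enrichment(toy["ppi"], toy["motifs_known"], toy["dmi_motif_domain"],
                             toy["domains"], strat, ShuffleConfig(n_shuffles=100, seed=1))
        assert len(res.potential) == 8
        assert 0.0 <= res.fdr <= 1.0
        assert 0.0 <= res.p_value.value <= 1.0
        if res.D is not None:
            assert res.enrichment == pytest.approx(1.0 + float(res.D.mean()), abs=1e-9)
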