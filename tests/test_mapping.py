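"""Strategy-dependent potential/predicted DMI mapping."""

from __future__ import annotations

import pytest

from dmienrich import (
    ConfigError,
    DMIStrategy,
    FixtureSpec,
    MotifOccurrenceTable,
    PPIDataset,
    PotentialDMI,
    StrategyMode,
    build_potential_dmis,
    extract_predicted_dmis,
    generate_fixture,
)
from dmienrich.mapping import count_predicted

from conftest import brute_force_potential, brute_force_predicted


class TestToyCrossProducts:
    """Hand-enumerated counts for the four stringency levels."""

    def test_elmi_protein(self, toy):
        pot = build_potential_dmis(
            toy["ppi"], None, toy["dmi_protein"], None,
            DMIStrategy(StrategyMode.ELMI_PROTEIN))
        assert len(pot) == 2

    def test_elmc_protein_known(self, toy):
        pot = build_potential_dmis(
            toy["ppi"], toy["motifs_known"], toy["dmi_motif_protein"], None,
            DMIStrategy(StrategyMode.ELMC_PROTEIN))
        assert len(pot) == 4

    def test_elmc_domain_known(self, toy):
        pot = build_potential_dmis(
            toy["ppi"], toy["motifs_known"], toy["dmi_motif_domain"], toy["domains"],
            DMIStrategy(StrategyMode.ELMC_DOMAIN))
        assert len(pot) == 8

    def test_elmc_domain_predicted(self, toy):
        pot = build_potential_dmis(
            toy["ppi"], toy["motifs_predicted"], toy["dmi_motif_domain"], toy["domains"],
            DMIStrategy(StrategyMode.ELMC_DOMAIN, occurrence_source="predicted"))
        assert len(pot) == 16


def test_schema_strategy_mismatch(toy):
    with pytest.raises(ConfigError, match="motif-domain"):
        build_potential_dmis(
            toy["ppi"], toy["motifs_known"], toy["dmi_protein"], toy["domains"],
            DMIStrategy(StrategyMode.ELMC_DOMAIN))


def test_carrier_absent_from_ppi_contributes_nothing(toy):
    motifs = MotifOccurrenceTable(rows=[("GHOST", "MOT_A")])
    pot = build_potential_dmis(
        toy["ppi"], motifs, toy["dmi_motif_domain"], toy["domains"],
        DMIStrategy(StrategyMode.ELMC_DOMAIN))
    assert pot == set()


def test_empty_motif_table_gives_empty_potential(toy):
    motifs = MotifOccurrenceTable(rows=[])
    pot = build_potential_dmis(
        toy["ppi"], motifs, toy["dmi_motif_domain"], toy["domains"],
        DMIStrategy(StrategyMode.ELMC_DOMAIN))
    assert pot == set()


class TestExtractPredicted:
    def test_realized_pair(self):
        pot = {PotentialDMI("A", "m1", "d1", "X")}
        pred = extract_predicted_dmis(pot, PPIDataset(pairs=[("A", "X")]))
        assert len(pred) == 1

    def test_asymmetry_respected(self):
        pot = {PotentialDMI("A", "m1", "d1", "X")}
        pred = extract_predicted_dmis(pot, PPIDataset(pairs=[("X", "A")]))
        assert len(pred) == 0

    def test_tuple_level_counting_exceeds_pair_level(self):
        # one observed pair carrying three distinct annotation routes
        pot = {
            PotentialDMI("A", "m1", "d1", "X"),
            PotentialDMI("A", "m2", "d1", "X"),
            PotentialDMI("A", "m1", "d2", "X"),
        }
        pred = extract_predicted_dmis(pot, PPIDataset(pairs=[("A", "X")]))
        assert len(pred) == 3
        assert pred.n_unique_mproteins == 1
        assert pred.n_unique_motifs == 2
        assert pred.n_unique_domains == 2
        assert pred.n_unique_dproteins == 1

    def test_removing_a_pair_never_increases_predicted(self, toy):
        pot = build_potential_dmis(
            toy["ppi"], toy["motifs_known"], toy["dmi_motif_domain"], toy["domains"],
            DMIStrategy(StrategyMode.ELMC_DOMAIN))
        full = len(extract_predicted_dmis(pot, toy["ppi"]))
        for i in range(len(toy["ppi"])):
            reduced = PPIDataset(
                pairs=[p for j, p in enumerate(toy["ppi"].pairs) if j != i])
            assert len(extract_predicted_dmis(pot, reduced)) <= full


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_brute_force_oracle_on_small_networks(seed):
    """Mapping equals a quadruple-loop enumeration on <=10-protein networks."""
    spec = FixtureSpec(n_mproteins=5, n_dproteins=5, n_motif_classes=3,
                       n_domain_classes=3, ppi_density=0.3, seed=seed)
    fx = generate_fixture(spec)
    for mode in ("elmi-protein", "elmc-protein", "elmc-domain"):
        strat = DMIStrategy(StrategyMode(mode))
        pot = build_potential_dmis(
            fx.ppi, fx.motifs, fx.dmi_for_mode(mode), fx.domains, strat)
        oracle = brute_force_potential(
            fx.ppi, fx.motifs, fx.dmi_for_mode(mode), fx.domains, mode)
        assert {tuple(t) for t in pot} == oracle
        pred = extract_predicted_dmis(pot, fx.ppi)
        assert {tuple(t) for t in pred.dmis} == brute_force_predicted(oracle, fx.ppi)
        assert count_predicted(pot, fx.ppi) == len(pred)


@pytest.mark.parametrize("seed", [0, 7, 21])
def test_stringency_monotonicity(seed):
    """Potential counts grow as the strategy relaxes (nested annotations)."""
    fx = generate_fixture(FixtureSpec(seed=seed, planted_fraction=0.3))
    counts = {}
    for mode in ("elmi-protein", "elmc-protein", "elmc-domain"):
        pot = build_potential_dmis(
            fx.ppi, fx.motifs, fx.dmi_for_mode(mode), fx.domains,
            DMIStrategy(StrategyMode(mode)))
        counts[mode] = len(pot)
        pred = extract_predicted_dmis(pot, fx.ppi)
        assert set(pred.dmis) <= pot
    assert counts["elmi-protein"] <= counts["elmc-protein"] <= counts["elmc-domain"]
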