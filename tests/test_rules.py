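"""The apportionment rules and per-compartment estimators."""

import pytest
from hypothesis import given, settings, strategies as st

from synaptome import (
    AISStats,
    DEFAULT_RULES,
    DendriticSegmentStats,
    NeuronMorphometry,
    SomaStats,
    SynapticRuleSet,
    apportion_population,
    estimate_ais_synapses,
    estimate_dendritic_synapses,
    estimate_somatic_synapses,
    estimate_whole_cell,
    validate_ruleset,
)


class TestDendriticEstimator:
    def test_reference_segment_breakdown(self):
        """100 um at 1.5 spines/um with default rules reproduces the
        published per-compartment expectations to 2 decimals."""
        bd = estimate_dendritic_synapses(DendriticSegmentStats(100.0, 1.5))
        assert bd.asym_spine == pytest.approx(160.35, abs=5e-3)
        assert bd.asym_shaft == pytest.approx(42.62, abs=5e-3)
        assert bd.sym_spine == pytest.approx(4.65, abs=5e-3)
        assert bd.sym_shaft == pytest.approx(10.35, abs=5e-3)
        assert bd.total == pytest.approx(217.97, abs=5e-3)
        assert bd.spine_synapses == pytest.approx(165.0, abs=5e-3)

    def test_empty_segment_is_all_zero(self):
        bd = estimate_dendritic_synapses(DendriticSegmentStats(0.0, 2.0))
        assert bd.total == 0.0
        assert (bd.asym_spine, bd.asym_shaft, bd.sym_spine, bd.sym_shaft) == (
            0.0,
            0.0,
            0.0,
            0.0,
        )

    def test_no_double_synapses_means_no_symmetric(self):
        """With p_double=0 every spine carries exactly one asymmetric
        synapse and the shaft count follows from rule 3 alone."""
        rules = SynapticRuleSet(p_double=0.0)
        bd = estimate_dendritic_synapses(DendriticSegmentStats(100.0, 1.5), rules)
        assert bd.asym_spine == pytest.approx(150.0)
        assert bd.asym_shaft == pytest.approx(150.0 * 21 / 79)
        assert bd.sym_spine == 0.0
        assert bd.sym_shaft == 0.0

    def test_zero_sym_spine_fraction_with_doubles_is_inconsistent(self):
        rules = SynapticRuleSet(f_sym_spine=0.0)
        with pytest.raises(ValueError, match="inconsistent"):
            estimate_dendritic_synapses(DendriticSegmentStats(10.0, 1.0), rules)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            DendriticSegmentStats(-1.0, 1.0)
        with pytest.raises(ValueError):
            DendriticSegmentStats(1.0, -1.0)
        with pytest.raises(ValueError):
            SynapticRuleSet(p_double=1.5)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        length=st.floats(0.0, 1e4),
        density=st.floats(0.0, 10.0),
        p_double=st.floats(0.0, 1.0),
        f_sym=st.floats(0.01, 1.0),
        f_asym=st.floats(0.01, 1.0),
    )
    def test_conservation_linearity_and_roundtrip(
        self, length, density, p_double, f_sym, f_asym
    ):
        """The four compartments sum to the total, scale linearly with
        length, and recover the rule fractions on each type."""
        rules = SynapticRuleSet(p_double=p_double, f_sym_spine=f_sym,
                                f_asym_spine=f_asym)
        bd = estimate_dendritic_synapses(
            DendriticSegmentStats(length, density), rules
        )
        parts = bd.asym_spine + bd.asym_shaft + bd.sym_spine + bd.sym_shaft
        assert parts == pytest.approx(bd.total, rel=1e-9)

        doubled = estimate_dendritic_synapses(
            DendriticSegmentStats(2 * length, density), rules
        )
        for attr in ("asym_spine", "asym_shaft", "sym_spine", "sym_shaft"):
            assert getattr(doubled, attr) == pytest.approx(
                2 * getattr(bd, attr), rel=1e-9, abs=1e-12
            )

        if bd.sym_spine > 0:
            assert bd.sym_spine / bd.symmetric == pytest.approx(f_sym, rel=1e-9)
        if bd.asym_spine > 0:
            assert bd.asym_spine / bd.asymmetric == pytest.approx(
                f_asym, rel=1e-9
            )


class TestSomaAndAIS:
    @pytest.mark.parametrize(
        "area,density,expected",
        [(0.0, 0.5, 0.0), (1000.0, 1.0, 1000.0), (850.0, 0.12, 102.0)],
    )
    def test_soma_product(self, area, density, expected):
        assert estimate_somatic_synapses(SomaStats(area, density)) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize(
        "length,density,expected",
        [(0.0, 0.7, 0.0), (40.0, 1.0, 40.0), (35.0, 0.6, 21.0)],
    )
    def test_ais_product(self, length, density, expected):
        assert estimate_ais_synapses(AISStats(length, density)) == pytest.approx(
            expected
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            SomaStats(-1.0, 0.1)
        with pytest.raises(ValueError):
            AISStats(10.0, -0.1)


def _worked_cell(**overrides):
    base = dict(
        cell_id="c1",
        l_ap=65.0,
        l_ba=50.0,
        spine_density=1.5,
        soma_area=0.0,
        soma_syn_density=0.0,
        ais_length=0.0,
        ais_syn_density=0.0,
    )
    base.update(overrides)
    return NeuronMorphometry(**base)


class TestWholeCell:
    def test_reduces_to_reference_segment(self):
        """115 um of dendrite minus the 15 um proximal exclusion leaves
        the 100 um reference segment."""
        est = estimate_whole_cell(_worked_cell())
        assert est.dendritic.total == pytest.approx(217.97, abs=5e-3)
        assert est.grand_total == pytest.approx(217.97, abs=5e-3)

    def test_all_zero_after_exclusion(self):
        est = estimate_whole_cell(_worked_cell(l_ap=15.0, l_ba=0.0))
        assert est.grand_total == 0.0

    def test_soma_and_ais_add_to_grand_total(self):
        est = estimate_whole_cell(
            _worked_cell(
                soma_area=1000.0,
                soma_syn_density=0.1,
                ais_length=40.0,
                ais_syn_density=0.5,
            )
        )
        assert est.soma_synapses == pytest.approx(100.0)
        assert est.ais_synapses == pytest.approx(20.0)
        assert est.grand_total == pytest.approx(217.97 + 120.0, abs=5e-3)
        # soma and AIS synapses are symmetric on pyramidal cells
        assert est.symmetric_total == pytest.approx(15.0 + 120.0, abs=5e-3)

    def test_dendrite_shorter_than_exclusion_names_cell(self):
        with pytest.raises(ValueError, match="c1"):
            estimate_whole_cell(_worked_cell(l_ap=5.0, l_ba=5.0))


class TestPopulation:
    def test_two_identical_cells_double_the_total(self):
        single = estimate_whole_cell(_worked_cell()).grand_total
        report = apportion_population([_worked_cell(), _worked_cell(cell_id="c2")])
        assert report.total_synapses == pytest.approx(2 * single, rel=1e-12)
        assert report.total_synapses == pytest.approx(435.94, abs=0.02)

    def test_singleton_population_equals_cell(self):
        report = apportion_population([_worked_cell()])
        assert report.total_synapses == pytest.approx(
            estimate_whole_cell(_worked_cell()).grand_total
        )
        assert report.mean_per_cell == report.total_synapses
        frame = report.to_frame()
        assert list(frame["cell_id"]) == ["c1"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            apportion_population([])


class TestRulesetValidation:
    def test_defaults_pass_with_known_symmetric_share(self):
        diag = validate_ruleset(DEFAULT_RULES)
        assert diag.passes
        assert diag.symmetric_share == pytest.approx(15.0 / 217.9747, abs=1e-4)

    def test_degenerate_rules_fail(self):
        diag = validate_ruleset(
            SynapticRuleSet(p_double=1.0, f_sym_spine=1.0, f_asym_spine=1.0)
        )
        assert not diag.passes
        assert diag.messages

    def test_no_doubles_flagged_below_band(self):
        diag = validate_ruleset(SynapticRuleSet(p_double=0.0))
        assert not diag.passes
        assert diag.symmetric_share == 0.0

    def test_inconsistent_rules_reported_not_raised(self):
        diag = validate_ruleset(SynapticRuleSet(f_sym_spine=0.0))
        assert not diag.passes
        assert diag.asymmetric_share is None
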