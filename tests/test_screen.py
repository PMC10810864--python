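"""CDI computation, the 24-node synergy screen, ICx and the p21 sweep."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pi3knet.network import DrugPerturbation
from pi3knet.presets import byl719
from pi3knet.screen import (
    EffectMeasurement,
    compute_cdi,
    dose_response,
    estimate_icx,
    p21_sweep,
    single_node_effect,
    synergy_screen,
)

positive_effects = st.floats(min_value=1e-3, max_value=1e3)


class TestComputeCDI:
    def test_independence_is_additive(self):
        rec = compute_cdi(
            EffectMeasurement("pS6", 0.6),
            EffectMeasurement("pS6", 0.5),
            EffectMeasurement("pS6", 0.3),
        )
        assert rec.CDI == pytest.approx(1.0)
        assert rec.label == "additive"

    def test_hand_arithmetic_case(self):
        rec = compute_cdi(
            EffectMeasurement("pRb", 0.5),
            EffectMeasurement("pRb", 0.5),
            EffectMeasurement("pRb", 0.2),
        )
        assert rec.CDI == pytest.approx(0.8)
        assert rec.synergy_index == pytest.approx(math.log2(0.8))
        assert rec.label == "synergistic"

    @settings(derandomize=True, max_examples=200)
    @given(e1=positive_effects, e2=positive_effects)
    def test_product_rule_always_gives_one(self, e1, e2):
        rec = compute_cdi(
            EffectMeasurement("x", e1),
            EffectMeasurement("x", e2),
            EffectMeasurement("x", e1 * e2),
        )
        assert rec.CDI == pytest.approx(1.0, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(e1=positive_effects, e2=positive_effects, e12=positive_effects,
           scale=st.floats(min_value=1e-2, max_value=1e2))
    def test_scale_invariance_of_unit_rescaling(self, e1, e2, e12, scale):
        # rescaling raw readouts by a common factor cancels in each E,
        # hence in the CDI; verified on the E-level identity
        base = compute_cdi(EffectMeasurement("x", e1),
                           EffectMeasurement("x", e2),
                           EffectMeasurement("x", e12))
        treated, vehicle = e1 * 3.7, 3.7
        rescaled = (treated * scale) / (vehicle * scale)
        assert rescaled == pytest.approx(e1, rel=1e-12)
        assert base.CDI == pytest.approx(e12 / (e1 * e2), rel=1e-12)

    def test_mismatched_readouts_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            compute_cdi(EffectMeasurement("a", 1.0),
                        EffectMeasurement("b", 1.0),
                        EffectMeasurement("a", 1.0))

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            EffectMeasurement("a", 0.0)


class TestSingleNodeEffect:
    def test_null_perturbation_has_unit_effect(self, parental_eq):
        level = DrugPerturbation("PDK1", mode="fraction", dose=0.0)
        out = single_node_effect(parental_eq, None, "PDK1", level, "pS6",
                                 t_eval=360.0)
        assert len(out) == 1
        assert out[0].E == pytest.approx(1.0, rel=1e-9)

    def test_pi3ka_inhibition_reduces_pS6(self, parental_eq):
        level = byl719(1.0)
        out = single_node_effect(parental_eq, None, "PI3Ka", level, "pS6",
                                 t_eval=2880.0)
        assert out[0].E <= 1.0

    def test_complete_inhibition_of_sole_producer_floors_readout(self):
        from pi3knet.presets import toy_pi3k_chain

        model = toy_pi3k_chain()
        from pi3knet.network import StimulusInput, equilibrate

        model = equilibrate(model, StimulusInput("IGF-1", 13.0))
        level = DrugPerturbation("AKT", mode="fraction", dose=1.0)
        out = single_node_effect(model, None, "AKT", level, "pS6",
                                 t_eval=720.0,
                                 stimulus=StimulusInput("IGF-1", 13.0))
        assert out[0].E < 0.05  # collapses to the basal floor


@pytest.fixture(scope="module")
def screen_result(parental_eq, small_ensemble):
    return synergy_screen(parental_eq, small_ensemble, t_eval=1440.0)


class TestSynergyScreen:
    def test_24_rows_per_readout(self, screen_result):
        for readout in screen_result.readouts:
            assert len(screen_result.table(readout)) == 24

    def test_ranking_is_permutation_of_registry(self, parental_eq,
                                                screen_result):
        for readout in screen_result.readouts:
            assert sorted(screen_result.ranking(readout)) == \
                sorted(parental_eq.perturbable_registry)

    def test_deterministic_rerun_identical_ranking(self, parental_eq,
                                                   small_ensemble,
                                                   screen_result):
        again = synergy_screen(parental_eq, small_ensemble, t_eval=1440.0)
        for readout in screen_result.readouts:
            assert again.ranking(readout) == screen_result.ranking(readout)
            for ct in again.co_targets:
                assert again.cdi[readout][ct] == \
                    screen_result.cdi[readout][ct]

    def test_pdk1_class_ranks_in_top_quartile(self, parental_eq):
        # demo-calibration regression: full-pathway co-inhibition (PDK1)
        # is among the most synergistic co-targets on every readout
        res = synergy_screen(parental_eq, None, t_eval=2880.0)
        for readout in res.readouts:
            rank = res.ranking(readout).index("PDK1") + 1
            assert rank <= 6, (readout, rank)

    def test_inert_co_target_gives_unit_cdi(self, toy_chain):
        # a node wired to affect nothing downstream of the readout: inhibit
        # the S6 output itself and read an upstream observable
        from pi3knet.network import StimulusInput, equilibrate

        model = equilibrate(toy_chain, StimulusInput("IGF-1", 13.0))
        # remove the pS6 -| receptor feedback so S6 is downstream-only
        model = model.with_updates({"K_fb": 1e9})
        res = synergy_screen(
            model, None,
            anchor=DrugPerturbation("PI3K", mode="fraction", dose=0.9),
            readouts=("pAKT",), t_eval=720.0, co_targets=["S6"],
            stimulus=StimulusInput("IGF-1", 13.0),
        )
        cdi = res.cdi["pAKT"]["S6"][0]
        assert cdi == pytest.approx(1.0, abs=1e-6)

    def test_anchor_with_itself_not_synergistic(self, parental_eq):
        # dose-additivity guard: PI3Kalpha plus PI3Kalpha at the same dose
        # must not be classified synergistic
        from pi3knet.screen import _readout_at

        vehicle = _readout_at(parental_eq, "pS6", [], 2880.0)
        one = _readout_at(parental_eq, "pS6", [byl719(1.0)], 2880.0)
        both = _readout_at(parental_eq, "pS6", [byl719(1.0), byl719(1.0)],
                           2880.0)
        E1 = E2 = one / vehicle
        E12 = both / vehicle
        assert E12 / (E1 * E2) >= 1.0 - 1e-9


class TestEstimateICx:
    def test_exact_hill_ic50(self):
        doses = np.linspace(0.0, 20.0, 401)
        resp = 1.0 / (1.0 + doses / 2.0)
        assert estimate_icx(doses, resp, 0.5) == pytest.approx(2.0, abs=1e-6)

    def test_exact_hill_ic75(self):
        # 1/(1 + d/2) = 0.25  =>  d = 6
        doses = np.linspace(0.0, 20.0, 2001)
        resp = 1.0 / (1.0 + doses / 2.0)
        assert estimate_icx(doses, resp, 0.75) == pytest.approx(6.0, abs=1e-4)

    def test_flat_response_is_an_error(self):
        with pytest.raises(ValueError, match="no crossing"):
            estimate_icx([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], 0.5)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            estimate_icx([0.0, 1.0, 2.0], [1.0, 0.4, 0.7], 0.5)

    def test_ic75_at_least_ic50(self, parental_eq):
        curve = dose_response(parental_eq, "PI3Ka",
                              [0.0, 0.02, 0.05, 0.2, 1.0, 5.0], "pAKT-S473",
                              t_eval=1440.0, mode="dose", K_I=0.05)
        assert curve.IC50 is not None
        if curve.IC75 is not None:
            assert curve.IC75 >= curve.IC50


class TestP21Sweep:
    def test_single_baseline_level_reproduces_unswept_model(
        self, parental_eq
    ):
        from pi3knet.screen import _readout_at

        sweep = p21_sweep(parental_eq, None, [1.0], t_eval=1440.0)
        direct = {
            r: _readout_at(parental_eq, r, [byl719(1.0)], 1440.0)
            for r in sweep["readouts"]
        }
        for ri, r in enumerate(sweep["readouts"]):
            assert sweep["values"][0, ri, 0] == pytest.approx(
                direct[r], rel=5e-2
            )

    def test_readouts_monotone_in_p21_level(self, parental_eq):
        # demo-calibration regression: higher p21 sustains cyclin D1, Rb and
        # S6 phosphorylation under 1 uM BYL719
        sweep = p21_sweep(parental_eq, None, [0.5, 1.0, 2.0, 4.0, 7.0],
                          t_eval=2880.0)
        for ri, r in enumerate(sweep["readouts"]):
            vals = sweep["values"][:, ri, 0]
            assert np.all(np.diff(vals) >= -1e-9), (r, vals)

    def test_table_dimensions_by_enumeration(self, parental_eq,
                                             small_ensemble):
        levels = [1.0, 3.0]
        sweep = p21_sweep(parental_eq, small_ensemble, levels,
                          t_eval=720.0)
        n_cells = sweep["values"].size
        assert n_cells == len(levels) * len(sweep["readouts"]) * \
            len(small_ensemble)

    def test_nonincreasing_levels_rejected(self, parental_eq):
        with pytest.raises(ValueError, match="increasing"):
            p21_sweep(parental_eq, None, [2.0, 1.0])
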