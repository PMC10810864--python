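"""Network model construction, simulation, perturbation and readouts."""

import numpy as np
import pytest

from pi3knet.network import (
    DrugPerturbation,
    SimulationError,
    Species,
    StimulusInput,
    apply_inhibition,
    conservation_check,
    equilibrate,
    extract_readouts,
    simulate_timecourse,
)
from pi3knet.presets import (
    build_parental_model,
    byl719,
    toy_birth_death,
    toy_chain3,
)

from conftest import rk4


class TestBuildParentalModel:
    def test_registry_has_24_co_targets(self, parental):
        assert len(parental.perturbable_registry) == 24
        assert len(set(parental.perturbable_registry)) == 24
        # the anchor is perturbable but not a screen co-target
        assert "PI3Ka" not in parental.perturbable_registry

    def test_required_nodes_present(self, parental):
        names = set(parental.species_names)
        # one representative species per pathway arm
        for req in ["pIGFR", "pErbB", "PIP3", "aPDK1", "ppAKT", "pERK",
                    "amTORC1", "amTORC2", "pS6", "aSGK1", "aSGK3", "pNDRG1",
                    "FOXO3", "aERa", "cMyc", "cycD1", "CycD1CDK46", "cycE",
                    "CycECDK2", "ppRb", "E2F", "p21", "TSC2", "aRac1",
                    "aPRex1"]:
            assert req in names, req

    def test_every_species_in_at_least_one_reaction(self, parental):
        # brute-force scan over the reaction list
        used = set()
        for r in parental.reactions:
            used.update(r.reactants)
            used.update(r.products)
            used.update(m.species for m in r.modifiers)
        assert set(parental.species_names) <= used

    def test_conservation_groups_verified_by_stoichiometry(self, parental):
        assert parental.conservation_groups
        for group in parental.conservation_groups:
            assert conservation_check(parental, group), group
        # a group containing a degraded species is rejected
        assert not conservation_check(parental, ("p21",))

    def test_negative_initial_abundance_rejected(self):
        with pytest.raises(ValueError, match="initial abundance"):
            Species("X", initial=-1.0)


class TestSimulate:
    def test_zero_rates_give_constant_trajectory(self, parental):
        frozen = parental.with_updates(
            {n: 0.0 for n in parental.parameters if n.startswith("k_")}
        )
        grid = np.linspace(0, 100, 11)
        traj = simulate_timecourse(frozen, StimulusInput("IGF-1", 13.0),
                                   grid=grid)
        y0 = frozen.initial_vector()
        assert np.allclose(traj.abundance_matrix, y0[:, None], atol=1e-9)

    def test_moiety_conservation_along_trajectory(self, parental_eq,
                                                  growth_medium):
        grid = np.linspace(0, 720, 25)
        traj = simulate_timecourse(parental_eq, growth_medium,
                                   drugs=[byl719(1.0)], grid=grid)
        for group in parental_eq.conservation_groups:
            total = sum(traj.series(s) for s in group)
            assert np.all(np.abs(total / total[0] - 1.0) < 1e-6), group

    def test_non_negative_abundances(self, parental_eq, growth_medium):
        traj = simulate_timecourse(parental_eq, growth_medium,
                                   drugs=[byl719(10.0)],
                                   grid=np.linspace(0, 2880, 49))
        assert traj.abundance_matrix.min() >= -1e-10

    def test_matches_rk4_oracle_on_toy_chain(self):
        model = toy_chain3(k1=1.0, k2=0.5)
        grid = np.linspace(0.0, 10.0, 21)
        traj = simulate_timecourse(model, stimulus=None, grid=grid,
                                   rtol=1e-10, atol=1e-12)

        def f(t, y):
            return [-1.0 * y[0], 1.0 * y[0] - 0.5 * y[1], 0.5 * y[1]]

        oracle = rk4(f, [1.0, 0.0, 0.0], grid, dt=1e-3)
        assert np.allclose(traj.abundance_matrix, oracle, rtol=1e-6,
                           atol=1e-9)

    def test_determinism_bitwise(self, parental_eq, growth_medium):
        grid = np.linspace(0, 360, 13)
        a = simulate_timecourse(parental_eq, growth_medium, grid=grid)
        b = simulate_timecourse(parental_eq, growth_medium, grid=grid)
        assert np.array_equal(a.abundance_matrix, b.abundance_matrix)

    def test_rejects_bad_grid(self, parental_eq):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate_timecourse(parental_eq, grid=np.array([0.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="72 h"):
            simulate_timecourse(parental_eq, grid=np.array([0.0, 80 * 60.0]))


class TestEquilibrate:
    def test_fixed_point_left_unchanged(self, parental_eq, growth_medium):
        again = equilibrate(parental_eq, growth_medium)
        assert np.allclose(again.initial_vector(),
                           parental_eq.initial_vector(), rtol=1e-6,
                           atol=1e-8)

    def test_birth_death_reaches_closed_form(self):
        model = toy_birth_death(k_s=0.2, k_d=0.1)
        eq = equilibrate(model, basal_stimulus=[])
        assert eq.initial_vector()[0] == pytest.approx(0.2 / 0.1, rel=1e-6)

    def test_builtin_preset_residual_below_threshold(self, parental_eq,
                                                     growth_medium):
        assert parental_eq.residual_norm(growth_medium) < 1e-8


class TestApplyInhibition:
    def test_null_perturbation_identical_trajectories(self, parental_eq,
                                                      growth_medium):
        null = DrugPerturbation("PDK1", mode="fraction", dose=0.0)
        grid = np.linspace(0, 360, 13)
        a = simulate_timecourse(parental_eq, growth_medium, grid=grid)
        b = simulate_timecourse(apply_inhibition(parental_eq, null),
                                growth_medium, grid=grid)
        assert np.array_equal(a.abundance_matrix, b.abundance_matrix)

    def test_full_pi3ka_inhibition_zeroes_its_pip3_flux(self, parental_eq,
                                                        growth_medium):
        # with f=1 the PIP3 level must fall to what PI3Kbeta alone sustains,
        # identical to deleting the alpha-catalyzed production reaction
        full = apply_inhibition(
            parental_eq, DrugPerturbation("PI3Ka", mode="fraction", dose=1.0)
        )
        no_alpha = parental_eq.with_updates({"k_PIP3_prod_a": 0.0})
        grid = np.linspace(0, 720, 25)
        a = simulate_timecourse(full, growth_medium, grid=grid)
        b = simulate_timecourse(no_alpha, growth_medium, grid=grid)
        assert np.allclose(a.series("PIP3"), b.series("PIP3"), rtol=1e-7,
                           atol=1e-9)

    def test_steady_state_pakt_monotone_in_inhibition_fraction(
        self, parental_eq, growth_medium
    ):
        values = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            drug = DrugPerturbation("PI3Ka", mode="fraction", dose=f)
            traj = simulate_timecourse(parental_eq, growth_medium,
                                       drugs=[drug],
                                       grid=np.linspace(0, 2880, 25))
            ro = extract_readouts(traj, {"pAKT": ["pAKT_T308", "ppAKT"]},
                                  times=[2880.0])
            values.append(ro["pAKT"][0])
        assert all(b <= a + 1e-9 for a, b in zip(values, values[1:])), values

    def test_drugs_compose_multiplicatively(self, parental_eq):
        half = DrugPerturbation("MEK", mode="fraction", dose=0.5)
        once = apply_inhibition(parental_eq, half)
        twice = apply_inhibition(once, half)
        assert once.drug_scales["pMEK"] == pytest.approx(0.5)
        assert twice.drug_scales["pMEK"] == pytest.approx(0.25)

    def test_unknown_target_rejected(self, parental_eq):
        with pytest.raises(KeyError, match="unknown perturbation target"):
            apply_inhibition(parental_eq,
                             DrugPerturbation("NOTANODE", dose=0.5))

    def test_dose_mode_activity_scale(self):
        drug = DrugPerturbation("PI3Ka", mode="dose", dose=1.0, K_I=0.05)
        assert drug.activity_scale == pytest.approx(1 / 21)


class TestReadouts:
    def test_identity_and_additive_mapping(self, parental_eq, growth_medium):
        grid = np.linspace(0, 120, 5)
        traj = simulate_timecourse(parental_eq, growth_medium, grid=grid)
        single = extract_readouts(traj, {"pS6": ["pS6"]})["pS6"]
        assert np.array_equal(single, traj.series("pS6"))
        summed = extract_readouts(
            traj, {"pAKT": ["pAKT_T308", "ppAKT"]}
        )["pAKT"]
        assert np.allclose(
            summed, traj.series("pAKT_T308") + traj.series("ppAKT")
        )

    def test_igf1_battery_times_available(self, parental_eq):
        # pAKT and pERK must be readable at 10, 30, 90 min of 13 nM IGF-1
        traj = simulate_timecourse(parental_eq, StimulusInput("IGF-1", 13.0),
                                   grid=np.linspace(0, 90, 10))
        ro = extract_readouts(
            traj,
            {k: parental_eq.observable_map[k] for k in ("pAKT", "pERK")},
            times=[10.0, 30.0, 90.0],
        )
        assert ro["pAKT"].shape == (3,)
        assert ro["pERK"].shape == (3,)
        assert np.all(ro["pAKT"] >= 0) and np.all(ro["pERK"] >= 0)

    def test_empty_mapping_rejected(self, parental_eq, growth_medium):
        traj = simulate_timecourse(parental_eq, growth_medium,
                                   grid=np.linspace(0, 60, 3))
        with pytest.raises(KeyError, match="maps to no species"):
            extract_readouts(traj, {"ghost": []})
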