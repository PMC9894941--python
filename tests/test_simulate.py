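"""Tests for the pulsatile-secretion, estrous and Ct generators."""

from __future__ import annotations

import numpy as np
import pytest

from lhpulse import (
    CtSimParams,
    EstrousSimParams,
    SimParams,
    default_presets,
    fold_changes,
    percent_diestrus,
    render_concentration,
    simulate_cohort,
    simulate_ct_table,
    simulate_estrous_log,
    simulate_profile,
    simulate_pulse_times,
)
from lhpulse.io import profiles_to_frame
from lhpulse.simulate import LN2, noiseless_concentration


class TestPulseTimes:
    def test_vanishing_rate_gives_no_pulses(self):
        params = SimParams(mean_ipi=1e9)
        assert len(simulate_pulse_times(params, seed=0)) == 0

    def test_deterministic_for_fixed_seed(self):
        params = SimParams(mean_ipi=20.0)
        a = simulate_pulse_times(params, seed=42)
        b = simulate_pulse_times(params, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_times_ascending_and_within_window(self):
        params = SimParams(mean_ipi=15.0, burn_in=60.0, duration=120.0)
        t = simulate_pulse_times(params, seed=3)
        assert np.all(np.diff(t) > 0)
        assert np.all((t >= -60.0) & (t <= 120.0))

    def test_mean_count_matches_renewal_expectation(self):
        """Stationary renewal: E[N] over [-burn_in, duration] = T / mean_ipi."""
        params = SimParams(mean_ipi=20.0, ipi_shape=10.0, burn_in=60.0)
        rng = np.random.default_rng(2026)
        counts = [len(simulate_pulse_times(params, rng)) for _ in range(2000)]
        expected = (params.duration + params.burn_in) / params.mean_ipi
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_halving_mean_ipi_increases_pulse_count(self):
        """Monte-Carlo one-sided comparison with a 3-SE margin."""
        rng = np.random.default_rng(11)
        fast = SimParams(mean_ipi=20.0)
        slow = SimParams(mean_ipi=40.0)
        nf = np.array([len(simulate_pulse_times(fast, rng)) for _ in range(1000)])
        ns = np.array([len(simulate_pulse_times(slow, rng)) for _ in range(1000)])
        se = np.sqrt(nf.var(ddof=1) / 1000 + ns.var(ddof=1) / 1000)
        assert nf.mean() - ns.mean() > 3 * se

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SimParams(mean_ipi=-1.0)
        with pytest.raises(ValueError):
            SimParams(ipi_shape=0.0)


class TestRender:
    def test_no_pulses_noiseless_is_flat_basal(self):
        params = SimParams(basal=0.7, noise_cv=0.0)
        prof = render_concentration([], [], params)
        assert len(prof) == 25  # floor(120/5)+1 grid points from t=0
        np.testing.assert_allclose(prof.values, 0.7)

    def test_one_half_life_halves_the_bolus(self):
        params = SimParams(basal=0.5, half_life=15.0, noise_cv=0.0)
        prof = render_concentration([0.0], [2.0], params)
        assert prof.values[prof.times == 15.0][0] == pytest.approx(1.5)

    def test_monotone_decay_after_single_pulse(self):
        params = SimParams(basal=0.0, noise_cv=0.0)
        prof = render_concentration([0.0], [3.0], params)
        assert np.all(np.diff(prof.values) < 0)

    def test_log_decay_slope_between_pulses(self):
        """Noiseless log(C - basal) falls linearly at ln2 / half_life."""
        params = SimParams(basal=0.4, half_life=12.0, noise_cv=0.0)
        pulses, boluses = np.array([-30.0, 10.0, 70.0]), np.array([2.0, 1.5, 2.5])
        t = np.linspace(15.0, 65.0, 200)  # strictly between pulses 2 and 3
        c = noiseless_concentration(t, pulses, boluses, params)
        slope = np.polyfit(t, np.log(c - params.basal), 1)[0]
        assert slope == pytest.approx(-LN2 / params.half_life, rel=1e-10)

    def test_floor_clips_reported_values(self):
        params = SimParams(basal=0.1, noise_cv=2.0, floor=0.32, seed=5)
        prof = render_concentration([0.0], [1.0], params, seed=5)
        assert np.all(prof.values >= 0.32)

    def test_negative_bolus_rejected(self):
        with pytest.raises(ValueError):
            render_concentration([0.0], [-1.0], SimParams())

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            render_concentration([0.0, 10.0], [1.0], SimParams())


class TestCohort:
    def test_bookkeeping(self):
        sims = simulate_cohort(default_presets("CHOW"), n_per_group=10, seed=0)
        assert len(sims) == 30
        groups = [s.profile.group for s in sims]
        assert groups.count("CON") == groups.count("LET") == 10

    def test_byte_identical_csv_for_same_master_seed(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            sims = simulate_cohort(default_presets("CHOW"), 3, seed=99)
            p = tmp_path / f"{run}.csv"
            profiles_to_frame([s.profile for s in sims]).to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_duplicate_presets_rejected(self):
        presets = default_presets("CHOW")
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort(presets + [presets[0]], 2, seed=0)

    def test_preset_ordering_enforced(self):
        from lhpulse.simulate import GroupPreset, _validate_preset_ordering

        bad = [
            GroupPreset("CON", "CHOW", SimParams(mean_ipi=20.0, basal=0.8)),
            GroupPreset("LET", "CHOW", SimParams(mean_ipi=60.0, basal=0.3)),
        ]
        with pytest.raises(ValueError):
            _validate_preset_ordering(bad)

    def test_let_trf_preset_equals_con(self):
        presets = {p.name: p for p in default_presets("CHOW")}
        assert presets["LET_TRF"].sim_params == presets["CON"].sim_params

    def test_truth_within_window(self):
        for sim in simulate_cohort(default_presets("CHOW"), 2, seed=1):
            t = sim.true_pulse_times
            assert np.all((t >= -60.0) & (t <= 120.0))
            assert len(t) == len(sim.true_boluses)


class TestEstrousSim:
    def test_full_arrest_is_absorbing(self):
        params = EstrousSimParams(arrest_bias=1.0, start_stage="D", seed=0)
        log = simulate_estrous_log(params)
        assert log.stages == ("D",) * 10
        assert percent_diestrus(log) == 100.0

    def test_uniform_chain_occupies_each_stage_equally(self):
        uniform = np.full((4, 4), 0.25)
        params = EstrousSimParams(
            days=10000, stage_transition=uniform, seed=7, start_stage="P"
        )
        log = simulate_estrous_log(params)
        pct = percent_diestrus(log)
        assert abs(pct - 25.0) < 3 * 100 * np.sqrt(0.25 * 0.75 / 10000)

    def test_seeded_reproducibility(self):
        params = EstrousSimParams(arrest_bias=0.4, seed=12)
        assert simulate_estrous_log(params).stages == simulate_estrous_log(params).stages

    def test_non_stochastic_matrix_rejected(self):
        m = np.full((4, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            EstrousSimParams(stage_transition=m)


class TestCtSim:
    def test_positive_effect_doubles_expression(self):
        params = CtSimParams(
            tissue="ovary",
            effects={"L19": {}, "g": {"LET": 1.0}},
            ct_noise_sd=0.0,
            n_per_group=4,
        )
        fc = {(r.group, r.gene): r for r in fold_changes(simulate_ct_table(params))}
        assert fc[("LET", "g")].mean_fold_change == pytest.approx(2.0)
        assert fc[("CON", "g")].mean_fold_change == pytest.approx(1.0)

    def test_zero_effects_give_unit_folds(self):
        params = CtSimParams(
            tissue="ovary", effects={"L19": {}, "g": {}}, ct_noise_sd=0.0
        )
        for r in fold_changes(simulate_ct_table(params)):
            assert r.mean_fold_change == pytest.approx(1.0)
            assert r.sem == pytest.approx(0.0)

    def test_negative_effect_halves_expression(self):
        params = CtSimParams(
            tissue="ovary", effects={"L19": {}, "g": {"LET": -1.0}}, ct_noise_sd=0.0
        )
        fc = {(r.group, r.gene): r for r in fold_changes(simulate_ct_table(params))}
        assert fc[("LET", "g")].mean_fold_change == pytest.approx(0.5)

    def test_missing_reference_gene_rejected(self):
        with pytest.raises(ValueError, match="reference gene"):
            CtSimParams(tissue="ovary", effects={"g": {"LET": 1.0}})

    def test_unstable_reference_rejected(self):
        with pytest.raises(ValueError, match="zero effects"):
            CtSimParams(tissue="ovary", effects={"L19": {"LET": 0.5}, "g": {}})

    def test_seeded_reproducibility(self):
        params = CtSimParams(seed=3)
        a = simulate_ct_table(params)
        b = simulate_ct_table(params)
        assert a == b


def test_profile_determinism_contract():
    """Same (params, seed) must reproduce identical sampled concentrations."""
    params = SimParams(mean_ipi=25.0, noise_cv=0.08, seed=17)
    a = simulate_profile(params)
    b = simulate_profile(params)
    np.testing.assert_array_equal(a.profile.values, b.profile.values)
    np.testing.assert_array_equal(a.true_pulse_times, b.true_pulse_times)
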