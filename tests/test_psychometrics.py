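import numpy as np
import pytest

from deformsense import (EnergyMap, KernelSpec, build_kernel, PsychoDataset,
                         FitError, fit_exponential, kernel_frequency_sweep,
                         simulate_observer, build_trial_schedule, TrialDesign,
                         EXP1_DESIGN, EXP2_DESIGN, EXP3_DESIGN)

DIRS = np.arange(24) * 15.0
POSITIONS = np.arange(61) * (4.97 / 61) + 4.97 / 122


def dataset_from(ncc, p, n=100):
    ncc = np.asarray(ncc, dtype=float)
    reports = np.round(np.asarray(p) * n).astype(int)
    return PsychoDataset(labels=[f"c{i}" for i in range(len(ncc))],
                         ncc=ncc, n_trials=np.full(len(ncc), n),
                         n_reports=reports)


def mixture_maps(f_gen=0.4, n_conditions=7, seed=7):
    """Condition maps that resemble a kernel at f_gen to varying degrees."""
    rng = np.random.default_rng(seed)
    base = build_kernel(KernelSpec(f=f_gen, phi=0.3), POSITIONS, DIRS).values
    maps = []
    for w in np.linspace(0.95, 0.05, n_conditions):
        noise = rng.normal(size=base.shape)
        values = w * base + (1 - w) * noise
        maps.append(EnergyMap(values=values - values.min(),
                              positions_deg=POSITIONS,
                              direction_labels_deg=DIRS))
    return maps


class TestExponentialFit:
    def test_noiseless_self_consistency(self):
        ncc = np.linspace(-0.2, 0.9, 7)
        p = 0.2 * np.exp(1.5 * ncc)
        ds = PsychoDataset(labels=list("abcdefg"), ncc=ncc,
                           n_trials=np.full(7, 10 ** 6),
                           n_reports=np.round(p * 10 ** 6).astype(int))
        fit = fit_exponential(ds)
        assert fit.a == pytest.approx(0.2, abs=1e-4)
        assert fit.b == pytest.approx(1.5, abs=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_constant_proportions_flagged_degenerate(self):
        ds = dataset_from(np.linspace(0, 1, 5), np.full(5, 0.5))
        fit = fit_exponential(ds)
        assert fit.degenerate and np.isnan(fit.r2)

    def test_degenerate_predictor_rejected(self):
        ds = dataset_from(np.full(5, 0.3), np.linspace(0.1, 0.9, 5))
        with pytest.raises(FitError, match="degenerate predictor"):
            fit_exponential(ds)

    def test_too_few_conditions_rejected(self):
        ds = dataset_from([0.1, 0.9], [0.2, 0.8])
        with pytest.raises(FitError):
            fit_exponential(ds)

    def test_r2_equals_residual_arithmetic(self, rng):
        ncc = np.linspace(-0.1, 0.8, 7)
        p = np.clip(0.15 * np.exp(2.0 * ncc) + rng.normal(0, 0.03, 7), 0, 1)
        ds = dataset_from(ncc, p, n=1000)
        fit = fit_exponential(ds)
        # recompute r² independently from the fitted curve
        pred = fit.a * np.exp(fit.b * ds.ncc)
        obs = ds.proportions
        ss_res = float(np.sum((obs - pred) ** 2))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        assert fit.r2 == pytest.approx(1.0 - ss_res / ss_tot, abs=1e-12)

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            PsychoDataset(labels=["a"], ncc=np.array([0.1]),
                          n_trials=np.array([10]), n_reports=np.array([11]))


class TestSyntheticObserver:
    def test_seeded_runs_are_identical(self):
        ncc = np.linspace(0, 0.8, 5)
        a = simulate_observer(0.1, 2.0, ncc, 50, seed=3)
        b = simulate_observer(0.1, 2.0, ncc, 50, seed=3)
        np.testing.assert_array_equal(a.n_reports, b.n_reports)

    def test_flat_link_pools_to_constant_probability(self):
        ncc = np.linspace(-0.5, 0.9, 8)
        ds = simulate_observer(0.3, 0.0, ncc, 10 ** 5, seed=0)
        pooled = ds.n_reports.sum() / ds.n_trials.sum()
        assert pooled == pytest.approx(0.3, abs=0.01)

    def test_large_n_parameter_recovery(self):
        ncc = np.linspace(-0.2, 0.9, 7)
        ds = simulate_observer(0.1, 2.0, ncc, 10 ** 5, seed=11)
        fit = fit_exponential(ds)
        assert fit.a == pytest.approx(0.1, rel=0.02)
        assert fit.b == pytest.approx(2.0, rel=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_observer(-0.1, 1.0, [0.1, 0.2, 0.3], 10, seed=0)
        with pytest.raises(ValueError):
            simulate_observer(0.1, 1.0, [0.1, 0.2, 0.3], 0, seed=0)


class TestSweep:
    def test_argmax_at_generating_frequency(self):
        maps = mixture_maps(f_gen=0.4)
        nccs = np.array([0.9, 0.75, 0.6, 0.45, 0.3, 0.15, 0.05])
        ds = simulate_observer(0.1, 2.5, nccs, 1000, seed=5)
        res = kernel_frequency_sweep(maps, ds)
        # refitting against the maps' own NCC at 0.4 recovers the best link
        assert res.best_frequency == 0.4

    def test_r2_values_equal_independent_fits(self):
        maps = mixture_maps()
        ds = simulate_observer(0.1, 2.5,
                               np.linspace(0.9, 0.05, 7), 500, seed=2)
        res = kernel_frequency_sweep(maps, ds, frequencies=(0.2, 0.4, 0.8))
        for _, row in res.table.iterrows():
            col = f"f={row.kernel_f_cpd:g}"
            ds_f = PsychoDataset(labels=ds.labels,
                                 ncc=res.nccs[col].to_numpy(),
                                 n_trials=ds.n_trials,
                                 n_reports=ds.n_reports)
            assert row.r2 == pytest.approx(fit_exponential(ds_f).r2,
                                           abs=1e-12)

    def test_nesting_never_lowers_max_r2(self):
        maps = mixture_maps(f_gen=0.4)
        ds = simulate_observer(0.1, 2.5,
                               np.linspace(0.9, 0.05, 7), 1000, seed=9)
        without = kernel_frequency_sweep(maps, ds, frequencies=(0.1, 1.6))
        with_gen = kernel_frequency_sweep(maps, ds,
                                          frequencies=(0.1, 0.4, 1.6))
        assert with_gen.table.r2.max() >= without.table.r2.max() - 1e-12

    def test_map_count_mismatch_rejected(self):
        ds = simulate_observer(0.1, 1.0, [0.1, 0.5, 0.9], 10, seed=0)
        with pytest.raises(ValueError, match="one map per"):
            kernel_frequency_sweep(mixture_maps()[:2], ds)


class TestTrialSchedules:
    @pytest.mark.parametrize("design,total", [
        (EXP1_DESIGN, 140), (EXP2_DESIGN, 420), (EXP3_DESIGN, 360)])
    def test_printed_design_totals(self, design, total):
        schedule = build_trial_schedule(design, seed=1)
        assert schedule.total_trials == total
        assert design.n_sessions * design.trials_per_session == total

    def test_within_session_balance(self):
        schedule = build_trial_schedule(EXP2_DESIGN, seed=4)
        per = schedule.trials.groupby(
            ["session", "grating_sf_cpd", "grating_orientation_deg"]).size()
        assert (per == EXP2_DESIGN.repetitions).all()

    def test_order_is_seeded_and_shuffled(self):
        a = build_trial_schedule(EXP1_DESIGN, seed=0).trials
        b = build_trial_schedule(EXP1_DESIGN, seed=0).trials
        c = build_trial_schedule(EXP1_DESIGN, seed=1).trials
        assert a.equals(b)
        assert not a.equals(c)
        # pseudo-randomized: not simply the factorial enumeration order
        first = a[a.session == 1]["deform_sf_cpd"].to_numpy()
        assert not np.array_equal(np.sort(first[:7]), first[:7])

    def test_design_validation(self):
        with pytest.raises(ValueError):
            TrialDesign(name="bad", n_sessions=0, factors={"f": (1,)})
        with pytest.raises(ValueError):
            TrialDesign(name="bad", n_sessions=1, factors={})


def test_direction_maps_explain_reports_better_than_baselined_energy():
    """Observers generated from direction-map NCCs are fitted at least as
    well by direction maps as by energy maps carrying a flat left/right
    baseline along the edge (the V1 vertical-orientation baseline)."""
    dmaps = mixture_maps(f_gen=0.2, seed=3)
    emaps = []
    for m in dmaps:
        values = m.values.copy()
        values[:, 0] += 2.0    # leftward channel baseline
        values[:, 12] += 2.0   # rightward channel baseline
        emaps.append(EnergyMap(values=values, positions_deg=m.positions_deg,
                               direction_labels_deg=m.direction_labels_deg))
    from deformsense import max_ncc_over_phase
    nccs = np.array([max_ncc_over_phase(0.2, m)[0] for m in dmaps])
    ds = simulate_observer(0.1, 2.5, nccs, 1000, seed=21)
    r2_dir = kernel_frequency_sweep(dmaps, ds).best_r2
    r2_energy = kernel_frequency_sweep(emaps, ds).best_r2
    assert r2_dir >= r2_energy
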