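"""Dwell extraction, mixture MLE, first-binding fits, count-based rates."""

import numpy as np
import pytest

import smkinetics as smk
from smkinetics import (
    ArrivalTimes,
    DwellSample,
    FrameInterval,
    Location,
    RecordingSet,
    extract_dwells,
    fit_biexponential,
    fit_first_binding,
    first_binding_times,
    kd_from_kinetics,
    photobleach_check,
    rate_from_counts,
    simulate_dwell_sample,
    summarize_initiation,
)
from smkinetics.intervals import dwell_sample_from_durations


def make_rec(intervals, n_frames=100, dt=0.5, locations=None):
    if locations is None:
        ids = sorted({iv.location_id for iv in intervals})
        locations = [Location(i, "dna") for i in ids]
    return RecordingSet(
        frame_interval_s=dt, n_frames=n_frames,
        locations=locations, intervals=intervals,
    )


class TestExtractDwells:
    def test_duration_and_censoring(self):
        rec = make_rec([
            FrameInterval(0, "rnap", 10, 20),
            FrameInterval(0, "rnap", 90, 100),
        ])
        s = extract_dwells(rec, "rnap")
        assert s.durations.tolist() == [5.0, 5.0]
        assert s.censored.tolist() == [False, True]

    def test_min_duration_filter_counts_discards(self):
        rec = make_rec([
            FrameInterval(0, "rnap", 1, 2),
            FrameInterval(0, "rnap", 10, 30),
        ])
        s = extract_dwells(rec, "rnap", min_duration_s=5.0)
        assert s.n == 1 and s.n_discarded_subframe == 1

    def test_unknown_channel_rejected(self):
        rec = make_rec([FrameInterval(0, "rnap", 1, 2)])
        with pytest.raises(ValueError, match="channel"):
            extract_dwells(rec, "tamra")

    def test_empirical_cdf_within_dkw_band(self):
        # mixture truth vs the extracted empirical CDF, DKW at alpha = 0.01
        a, t1, t2, dt = 0.91, 2.6, 29.7, 0.5
        d, _ = simulate_dwell_sample(a, t1, t2, 20_000, dt, seed=8)
        n = d.size
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))
        # evaluate at frame boundaries, where the quantized empirical CDF
        # coincides exactly with the truncated continuous CDF
        xs = np.arange(2, 300) * dt
        ecdf = np.searchsorted(np.sort(d), xs + 1e-9) / n
        surv = lambda t: a * np.exp(-t / t1) + (1 - a) * np.exp(-t / t2)
        truth = (surv(dt) - surv(xs)) / surv(dt)
        assert np.max(np.abs(ecdf - truth)) < eps


class TestBiexpFit:
    def test_recovery_at_reference_scale(self):
        d, nd = simulate_dwell_sample(0.91, 2.6, 29.7, 2576, 0.5, seed=9)
        fit = fit_biexponential(dwell_sample_from_durations(d, 0.5, nd),
                                n_boot=100, seed=1)
        assert fit.a == pytest.approx(0.91, abs=max(3 * fit.se_a, 0.03))
        assert fit.tau1_s == pytest.approx(2.6, abs=max(3 * fit.se_tau1, 0.4))
        assert fit.tau2_s == pytest.approx(29.7, abs=max(3 * fit.se_tau2, 3.0))

    def test_single_phase_flags_tau2(self):
        d, nd = simulate_dwell_sample(1.0, 3.0, 3.0, 2000, 0.1, seed=10)
        fit = fit_biexponential(dwell_sample_from_durations(d, 0.1, nd), n_boot=0)
        assert "tau2_unidentifiable" in fit.flags
        assert fit.mean_s == pytest.approx(3.0, rel=0.1)

    def test_likelihood_dominance_over_truth(self):
        # the fitted likelihood is at least the likelihood at the truth
        from smkinetics.intervals import _biexp_nll
        from scipy.special import logit

        d, nd = simulate_dwell_sample(0.91, 2.6, 29.7, 2000, 0.5, seed=11)
        s = dwell_sample_from_durations(d, 0.5, nd)
        fit = fit_biexponential(s, n_boot=0)
        nll_truth = _biexp_nll(
            [logit(0.91), np.log(2.6), np.log(29.7 - 2.6)],
            s.durations, s.censored, s.frame_interval_s,
            s.window_offset_s, s.truncation_s,
        )
        assert fit.loglik >= -nll_truth - 1e-6

    def test_censored_dwells_enter_as_survival_terms(self):
        # heavy right-censoring must not bias tau downward
        rng = np.random.default_rng(12)
        t = rng.exponential(10.0, 4000)
        cens = t > 15.0
        s = DwellSample(
            durations=np.where(cens, 15.0, np.ceil(t / 0.1) * 0.1),
            frame_interval_s=0.1, censored=cens, min_observed_s=0.1,
        )
        fit = fit_biexponential(s, n_boot=0)
        assert fit.mean_s == pytest.approx(10.0, rel=0.1)


class TestFirstBinding:
    def test_first_times_and_censoring(self):
        rec = make_rec(
            [FrameInterval(0, "rnap", 4, 9)],
            locations=[Location(0, "dna"), Location(1, "dna"), Location(2, "control")],
        )
        fb = first_binding_times(rec, "rnap")
        assert fb["dna"].times.tolist() == [2.0, 50.0]
        assert fb["dna"].censored.tolist() == [False, True]
        assert fb["control"].censored.all()

    def test_reduces_to_exponential_mle_without_background(self):
        rng = np.random.default_rng(13)
        conc = 1e-9
        t = rng.exponential(1.0 / (2.2e6 * conc), 500)
        dna = ArrivalTimes(t, np.zeros(t.size, dtype=bool))
        ctrl = ArrivalTimes(np.full(100, t.max()), np.ones(100, dtype=bool))
        fit = fit_first_binding(dna, ctrl, conc_M=conc, fix_a_f=1.0,
                                fix_k_bkgnd=0.0, n_boot=0)
        assert fit.k_a == pytest.approx(1.0 / (conc * t.mean()), rel=1e-4)

    def test_concentration_rescaling_leaves_k_a_invariant(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(400.0, 400)
        dna = ArrivalTimes(t, np.zeros(t.size, dtype=bool))
        ctrl = ArrivalTimes(np.full(50, 2000.0), np.ones(50, dtype=bool))
        f1 = fit_first_binding(dna, ctrl, conc_M=1e-9, fix_a_f=1.0,
                               fix_k_bkgnd=0.0, n_boot=0)
        f2 = fit_first_binding(
            ArrivalTimes(t / 2, np.zeros(t.size, dtype=bool)), ctrl,
            conc_M=2e-9, fix_a_f=1.0, fix_k_bkgnd=0.0, n_boot=0,
        )
        assert f2.k_a == pytest.approx(f1.k_a, rel=1e-3)

    def test_mle_agrees_with_cdf_least_squares_oracle(self):
        # independent route: unweighted nonlinear LS on the empirical CDF
        from scipy.optimize import curve_fit

        cfg = smk.SimConfig(seed=15, n_dna_locations=300, n_control_locations=300,
                            greb_conc_M=0.0)
        rec, _ = smk.simulate_cosmos_recording(cfg)
        fb = first_binding_times(rec, "rnap")
        fit = fit_first_binding(fb["dna"], fb["control"], conc_M=1e-9, n_boot=0)

        # cumulative bound fractions over the whole location sets, including
        # the late-time plateau that pins the active fraction
        grid = np.linspace(10.0, rec.duration_s, 150)

        def cumfrac(at):
            return np.array([np.mean((at.times <= g) & ~at.censored) for g in grid])

        # stage 1: background rate from the control curve alone
        kb_ls, _ = curve_fit(
            lambda tt, kb: 1 - np.exp(-kb * 1e-9 * tt), grid, cumfrac(fb["control"]),
            p0=[4e4], bounds=([0], [1e7]), maxfev=20000,
        )

        # stage 2: DNA curve with background fixed, as in the joint MLE
        def model(tt, ka, af):
            lam, lb = (ka + kb_ls[0]) * 1e-9, kb_ls[0] * 1e-9
            return af * (1 - np.exp(-lam * tt)) + (1 - af) * (1 - np.exp(-lb * tt))

        popt, _ = curve_fit(model, grid, cumfrac(fb["dna"]), p0=[2e6, 0.9],
                            bounds=([1e4, 0], [1e8, 1]), maxfev=20000)
        assert fit.k_a == pytest.approx(popt[0], rel=0.25)
        assert fit.a_f == pytest.approx(popt[1], abs=0.1)


class TestCountsAndSummaries:
    @pytest.mark.parametrize(
        "n,t,c,k,se",
        [
            (47, 1121.0, 10e-9, 0.42e7, 0.06e7),
            (32, 168 * 1342.0, 10e-9, 1.4e4, 0.25e4),
            (0, 100.0, 1e-9, 0.0, 0.0),
        ],
    )
    def test_rate_from_counts(self, n, t, c, k, se):
        r = rate_from_counts(n, t, c)
        assert r.k == pytest.approx(k, rel=0.02)
        assert r.se == pytest.approx(se, rel=0.05, abs=1e-12)

    def test_kd_from_kinetics(self):
        assert kd_from_kinetics(0.94e7, 5.3) * 1e9 == pytest.approx(20.1, abs=0.1)
        assert kd_from_kinetics(1.5e7, 5.6) * 1e9 == pytest.approx(11.9, abs=0.1)
        assert kd_from_kinetics(1e15, 5.0) < 1e-15

    def test_fold_inhibition_from_printed_averages(self):
        reps = {"ref": [(5.8, 0.6)], "dksa": [(1.7, 0.6)]}
        s = summarize_initiation(reps, "ref")
        assert s.fold_inhibition["dksa"][0] == pytest.approx(3.4, abs=0.05)
        reps = {"ref": [(5.5, 0.7)], "greb_ppgpp": [(0.9, 0.5)]}
        s = summarize_initiation(reps, "ref")
        assert s.fold_inhibition["greb_ppgpp"][0] == pytest.approx(6.1, abs=0.05)

    def test_self_fold_is_one_and_zero_rejected(self):
        s = summarize_initiation({"ref": [2.0, 4.0]}, "ref")
        assert s.fold_inhibition["ref"][0] == 1.0
        with pytest.raises(ValueError):
            summarize_initiation({"ref": [0.0]}, "ref")


class TestInitiation:
    @staticmethod
    def expected_overall_rate(cfg):
        """Analytic oracle for the measured per-location initiation rate.

        Visits arrive at rate r = k1 [RNAP]; each commits with probability
        p = 1 - E[exp(-k_init T)] (Laplace transform of the hyperexponential
        dwell); the overall hazard at low promoter occupancy is ~ r p, times
        the probability the spawned probe dwell passes the 5 s filter.
        """
        spec = smk.scheme_dwell_params(cfg.rates_free)
        lam1, lam2 = 1 / spec.tau1_s, 1 / spec.tau2_s
        k = cfg.k_init_si
        p = 1 - (spec.a * lam1 / (lam1 + k) + (1 - spec.a) * lam2 / (lam2 + k))
        r = cfg.rates_free.k1 * cfg.rnap_conc_M
        p_probe = np.exp(-5.0 / cfg.probe_dwell_mean_s)
        return r * p * p_probe

    def test_recovery_against_renewal_oracle(self):
        cfg = smk.SimConfig(
            seed=16, n_dna_locations=400, n_control_locations=400,
            n_frames=3600, frame_interval_s=1.0,
            greb_conc_M=0.0, k_init_si=0.08,
            k_bkgnd_Msi={"rnap": 0.037e6, "greb": 0.0, "probe": 1e-5 / 10e-9},
        )
        rec, _ = smk.simulate_cosmos_recording(cfg)
        fit = smk.initiation_rate(rec, min_duration_s=5.0, n_boot=0)
        expect = self.expected_overall_rate(cfg)  # ~ 4.5e-4 s^-1
        assert fit.k_a == pytest.approx(expect, rel=0.3)
        assert fit.k_bkgnd < 3e-5  # background resolved near its 1e-5 truth

    def test_fixed_active_fraction_consistency(self):
        cfg = smk.SimConfig(
            seed=17, n_dna_locations=400, n_control_locations=400,
            n_frames=3600, frame_interval_s=1.0,
            greb_conc_M=0.0, k_init_si=0.08,
        )
        rec, _ = smk.simulate_cosmos_recording(cfg)
        free = smk.initiation_rate(rec, n_boot=0)
        fixed = smk.initiation_rate(rec, fix_a_f=0.95, n_boot=0)
        assert fixed.k_a == pytest.approx(free.k_a, rel=0.25)

    def test_missing_controls_flagged(self):
        cfg = smk.SimConfig(seed=18, n_dna_locations=20, n_control_locations=0,
                            k_init_si=6e-4)
        rec, _ = smk.simulate_cosmos_recording(cfg)
        with pytest.raises(ValueError, match="control"):
            smk.initiation_rate(rec)


class TestPhotobleach:
    def test_verdicts(self):
        quiet = DwellSample(durations=np.full(50, 100.0), frame_interval_s=1.0,
                            censored=np.ones(50, dtype=bool))
        assert photobleach_check(quiet, tau2_s=30.0).negligible
        rng = np.random.default_rng(19)
        fast = DwellSample(durations=rng.exponential(30.0, 400), frame_interval_s=1.0)
        v = photobleach_check(fast, tau2_s=30.0)  # k_bl ~ 1/tau2
        assert not v.negligible

    def test_bleaching_shortens_slow_phase(self):
        # competing exponentials: apparent tau2 -> (1/tau2 + k_bl)^-1
        k_bl = 1.0 / 30.0
        cfg_on = smk.SimConfig(seed=20, n_dna_locations=400, n_control_locations=0,
                               greb_conc_M=0.0, bleach_rate_si=k_bl,
                               k_bkgnd_Msi={"rnap": 0.0, "greb": 0.0, "probe": 0.0})
        rec, _ = smk.simulate_cosmos_recording(cfg_on)
        fit = fit_biexponential(extract_dwells(rec, "rnap"), n_boot=0)
        expected = 1.0 / (1.0 / 29.7 + k_bl)  # ~ 14.9 s
        assert fit.tau2_s == pytest.approx(expected, rel=0.25)
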