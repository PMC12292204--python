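import numpy as np
import pytest

from eegcam.interpret import band_power
from eegcam.synth import (BandSignature, CohortSpec, Epoch, EpochSpec,
                          add_artifact, generate_background, generate_cohort,
                          group_task_totals, plant_band_signature, trial_plan)


def zero_epoch(spec, group="A+P-", task="MSIT"):
    return Epoch(np.zeros((spec.n_channels, spec.n_samples)), "S01", group, task)


class TestEpochSpec:
    def test_default_geometry(self):
        spec = EpochSpec()
        assert spec.n_samples == 320
        assert spec.n_channels == 60

    def test_inconsistent_window_rejected(self):
        with pytest.raises(ValueError):
            EpochSpec(fs=250, t_start=-80, t_end=1200, n_samples=321)

    def test_times_span_window(self):
        t = EpochSpec().times
        assert t[0] == pytest.approx(-0.080)
        assert len(t) == 320


class TestBackground:
    def test_zero_scale_gives_zeros(self, epoch_spec):
        assert not generate_background(epoch_spec, 1.0, 0.0, seed=1).any()

    def test_determinism_bit_identical(self, epoch_spec):
        a = generate_background(epoch_spec, 1.0, 10.0, seed=7)
        b = generate_background(epoch_spec, 1.0, 10.0, seed=7)
        assert np.array_equal(a, b)

    def test_zero_mean_and_rms_scale(self, epoch_spec):
        x = generate_background(epoch_spec, 1.0, 10.0, seed=3)
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(x.std(axis=1), 10.0)

    def test_spectral_slope_matches_exponent(self):
        # long single-channel epochs; average periodogram over 100 seeds,
        # then fit the log-log slope between 1 and 60 Hz
        from scipy.signal import periodogram
        spec = EpochSpec(fs=250.0, t_start=0.0, t_end=16384.0,
                         n_channels=1, n_samples=4096)
        psds = []
        for seed in range(100):
            x = generate_background(spec, 1.0, 1.0, seed=seed)
            f, p = periodogram(x[0], fs=spec.fs, window="boxcar")
            psds.append(p)
        pm = np.mean(psds, axis=0)
        sel = (f >= 1.0) & (f <= 60.0)
        slope = np.polyfit(np.log(f[sel]), np.log(pm[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.3)

    def test_negative_args_rejected(self, epoch_spec):
        with pytest.raises(ValueError):
            generate_background(epoch_spec, -1.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_background(epoch_spec, 1.0, -1.0, seed=0)


class TestPlantSignature:
    def test_zero_amplitude_leaves_epoch_unchanged(self, epoch_spec, montage60):
        ep = zero_epoch(epoch_spec)
        sig = BandSignature("alpha", ("parietal",), 0.0)
        out = plant_band_signature(ep, sig, montage60, epoch_spec, seed=1)
        assert np.array_equal(out.data, ep.data)

    def test_only_target_region_touched(self, epoch_spec, montage60):
        ep = zero_epoch(epoch_spec)
        sig = BandSignature("alpha", ("parietal",), 5.0)
        out = plant_band_signature(ep, sig, montage60, epoch_spec, seed=1)
        idx = montage60.channels_in_region("parietal")
        other = np.setdiff1d(np.arange(60), idx)
        assert not out.data[other].any()
        assert np.all(out.data[idx].std(axis=1) > 0)

    def test_in_band_power_is_half_amplitude_squared(self, epoch_spec, montage60):
        # Parseval: sinusoid of amplitude A carries A^2/2 power; averaged
        # over random in-band frequencies (leakage at band edges)
        A = 4.0
        sig = BandSignature("alpha", ("parietal",), A)
        idx = montage60.channels_in_region("parietal")
        powers = []
        for seed in range(50):
            out = plant_band_signature(zero_epoch(epoch_spec), sig, montage60,
                                       epoch_spec, seed=seed)
            powers.append(band_power(out, "alpha", epoch_spec)[idx].mean())
        assert np.mean(powers) == pytest.approx(A ** 2 / 2, rel=0.2)

    def test_theta_signature_raises_posterior_over_frontal_power(
            self, epoch_spec, montage60):
        sig = BandSignature("theta", ("parietal", "temporal"), 5.0)
        post = montage60.channels_in_region(("parietal", "temporal"))
        front = montage60.channels_in_region("frontal")
        post_p, front_p = [], []
        for seed in range(50):
            bg = generate_background(epoch_spec, 1.0, 10.0, seed=seed)
            ep = Epoch(bg, "S01", "A+P-", "MSIT")
            out = plant_band_signature(ep, sig, montage60, epoch_spec, seed=seed)
            bp = band_power(out, "theta", epoch_spec)
            post_p.append(bp[post].mean())
            front_p.append(bp[front].mean())
        assert np.mean(post_p) > np.mean(front_p)

    def test_empty_region_is_error(self, epoch_spec):
        from eegcam.montage import build_montage
        m1 = build_montage(1)  # central only
        spec1 = EpochSpec(n_channels=1)
        ep = Epoch(np.zeros((1, 320)), "S01", "N", "MSIT")
        sig = BandSignature("alpha", ("parietal",), 1.0)
        with pytest.raises(ValueError):
            plant_band_signature(ep, sig, m1, spec1, seed=0)


class TestArtifacts:
    def test_zero_amplitude_identity(self, epoch_spec, montage60):
        ep = zero_epoch(epoch_spec)
        out = add_artifact(ep, "ocular", 0.0, montage60, epoch_spec, seed=1)
        assert np.array_equal(out.data, ep.data)

    def test_unknown_kind_rejected(self, epoch_spec, montage60):
        with pytest.raises(ValueError):
            add_artifact(zero_epoch(epoch_spec), "cardiac", 10.0, montage60,
                         epoch_spec, seed=1)

    def test_ocular_delta_power_concentrates_prefrontally(
            self, epoch_spec, montage60):
        ep = zero_epoch(epoch_spec)
        out = add_artifact(ep, "ocular", 200.0, montage60, epoch_spec, seed=2)
        delta = band_power(out, "delta", epoch_spec)
        frontal = set(montage60.channels_in_region("frontal"))
        # confined to frontal channels ...
        untouched = [i for i in range(60) if i not in frontal]
        assert np.allclose(delta[untouched], 0.0)
        # ... and strongest at the prefrontal pole
        top3 = set(np.argsort(-delta)[:3])
        pole = {montage60.index(n) for n in ("Fp1", "Fpz", "Fp2")}
        assert top3 == pole

    def test_emg_beta_burst_on_temporal_channels_only(
            self, epoch_spec, montage60):
        ep = zero_epoch(epoch_spec)
        out = add_artifact(ep, "emg", 50.0, montage60, epoch_spec, seed=3)
        beta = band_power(out, "beta", epoch_spec)
        temporal = montage60.channels_in_region("temporal")
        other = np.setdiff1d(np.arange(60), temporal)
        assert np.allclose(beta[other], 0.0)
        assert np.all(beta[temporal] > 0)
        # high-frequency burst: little energy below 4 Hz relative to beta
        delta = band_power(out, "delta", epoch_spec)
        assert delta[temporal].mean() < 0.05 * beta[temporal].mean()


class TestCohort:
    def test_default_cohort_bookkeeping_matches_study_counts(self):
        cohort = CohortSpec()
        totals = group_task_totals(cohort)
        assert totals["N"] == {"MSIT": 3176, "STMT": 2442}
        assert totals["A+P-"] == {"MSIT": 2720, "STMT": 2151}
        assert totals["A+P+"] == {"MSIT": 1738, "STMT": 1364}
        plan = trial_plan(cohort)
        for g, per_task in totals.items():
            for task, total in per_task.items():
                counts = plan[g][task]
                assert sum(counts) == total
                assert max(counts) - min(counts) <= 1

    def test_scaled_generation_keeps_51_subjects(self, epoch_spec):
        ds = generate_cohort(CohortSpec(scale=0.005, master_seed=1), epoch_spec)
        assert len(ds.subjects) == 21 + 18 + 12 == 51
        plan = trial_plan(CohortSpec(scale=0.005))
        for g in ("N", "A+P-", "A+P+"):
            expected = sum(sum(v) for v in plan[g].values())
            assert ds.n_trials(groups=(g,)) == expected

    def test_zero_trials_degenerate(self, epoch_spec):
        cohort = CohortSpec(scale=0.0, master_seed=1)
        ds = generate_cohort(cohort, epoch_spec)
        assert len(ds.subjects) == 51
        assert ds.n_trials() == 0

    def test_determinism_bit_identical(self, mini_spec):
        gs = {"N": 3, "A+P-": 3, "A+P+": 2}
        tt = {g: {"MSIT": 6, "STMT": 6} for g in gs}
        kw = dict(group_sizes=gs, trial_totals=tt, master_seed=11)
        a = generate_cohort(CohortSpec(**kw), mini_spec)
        b = generate_cohort(CohortSpec(**kw), mini_spec)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id
            for ea, eb in zip(sa.epochs, sb.epochs):
                assert np.array_equal(ea.data, eb.data)

    def test_subject_level_variance_component(self, mini_spec, montage60):
        # amplitude_sd > 0 must inflate the between-subject variance of
        # subject-mean in-band power relative to amplitude_sd = 0
        def subject_means(sd, seed):
            gs = {"N": 0, "A+P-": 10, "A+P+": 0}
            tt = {"A+P-": {"MSIT": 60, "STMT": 0}}
            sig = BandSignature("alpha", ("parietal",), 6.0, sd, 0.5)
            cohort = CohortSpec(group_sizes=gs, trial_totals=tt,
                                signatures={"A+P-": [sig]}, master_seed=seed,
                                artifact_rates={})
            ds = generate_cohort(cohort, mini_spec)
            idx = montage60.channels_in_region("parietal")
            return [np.mean([band_power(ep, "alpha", mini_spec)[idx].mean()
                             for ep in s.epochs]) for s in ds.subjects]

        var_hier = np.var(subject_means(3.0, 5), ddof=1)
        var_flat = np.var(subject_means(0.0, 5), ddof=1)
        assert var_hier > var_flat

    def test_planted_power_monotone_in_amplitude(self, mini_spec, montage60):
        # in-band target-region power strictly increases across 3 amplitudes
        sigs = {a: BandSignature("theta", ("temporal",), a) for a in (1.0, 3.0, 9.0)}
        idx = montage60.channels_in_region("temporal")
        means = {}
        for a, sig in sigs.items():
            vals = []
            for seed in range(30):
                bg = generate_background(mini_spec, 1.0, 10.0, seed=seed)
                ep = Epoch(bg, "S01", "A+P-", "MSIT")
                out = plant_band_signature(ep, sig, montage60, mini_spec,
                                           seed=1000 + seed)
                vals.append(band_power(out, "theta", mini_spec)[idx].mean())
            means[a] = np.mean(vals)
        assert means[1.0] < means[3.0] < means[9.0]

    def test_invalid_cohort_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(group_sizes={"N": -1, "A+P-": 2, "A+P+": 2})
        with pytest.raises(ValueError):
            CohortSpec(artifact_rates={"ocular": 1.5})
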