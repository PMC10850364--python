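import numpy as np
import pytest

import neoconn as nc
from neoconn.exceptions import ConfigurationError, DimensionError
from neoconn.synthetic import cohort_frame, simulate_subject


class TestLatentSignals:
    def test_band_limited_and_zero_mean(self, fast_config):
        lat = nc.simulate_latent_signals(8, fast_config)
        assert lat.shape == (8, fast_config.n_samples_fnirs)
        np.testing.assert_allclose(lat.mean(axis=1), 0.0, atol=1e-10)
        freqs = np.fft.rfftfreq(lat.shape[1], 1 / fast_config.fs_fnirs)
        power = np.abs(np.fft.rfft(lat, axis=1)) ** 2
        inband = (freqs >= 0.01) & (freqs <= 0.1)
        frac = power[:, inband].sum() / power.sum()
        assert frac > 0.95

    def test_deterministic_given_seed(self, fast_config):
        a = nc.simulate_latent_signals(8, fast_config)
        b = nc.simulate_latent_signals(8, fast_config)
        np.testing.assert_array_equal(a, b)

    def test_planted_community_correlation_gap(self):
        """Within/between correlation gap tracks the generating covariance.

        Band-limited series carry ~2 * bandwidth * duration effective samples
        (about 65 at the defaults), so single-seed correlations fluctuate by
        ~0.12; the gap is checked on the across-seed average.
        """
        gaps = []
        for seed in range(10):
            cfg = nc.SimulationConfig(
                seed=seed, rho_within=0.8, rho_between=0.0, rho_subject_sd=0.0
            )
            lat = nc.simulate_latent_signals(8, cfg)  # 3662 samples at defaults
            c = np.corrcoef(lat)
            within = np.mean(
                [c[i, j] for comm in cfg.communities for i in comm for j in comm if i < j]
            )
            between = np.mean(
                [c[i, j] for i in cfg.communities[0] for j in cfg.communities[1]]
            )
            gaps.append(within - between)
        assert np.mean(gaps) == pytest.approx(0.8, abs=0.1)

    def test_infeasible_band_rejected(self):
        with pytest.raises(ConfigurationError):
            nc.SimulationConfig(latent_band=(0.1, 0.01))
        with pytest.raises(ConfigurationError):
            nc.SimulationConfig(latent_band=(0.01, 8.0))


class TestFnirsForwardModel:
    def test_full_sharing_makes_lobe_channels_identical(self, fast_config, rng):
        cfg = nc.SimulationConfig(
            n_per_group=2, duration_s=120.0, shared_fraction=1.0, noise_sd=0.0
        )
        lat = nc.simulate_latent_signals(8, cfg, rng)
        layout = nc.default_montage()
        hbo, _ = nc.simulate_fnirs_recording(lat, layout, cfg, rng)
        groups = layout.channel_groups()
        for members in groups.values():
            base = hbo.data[members[0]]
            for ch in members[1:]:
                r = np.corrcoef(base, hbo.data[ch])[0, 1]
                assert r == pytest.approx(1.0)

    def test_zero_sharing_decorrelates_channels(self):
        """Independent channels: signed correlations centered on zero.

        With ~65 effective samples (band-limited series) the null |r| spread
        is ~0.12, so the signed mean and a matching magnitude bound are
        checked rather than a white-noise-scale one.
        """
        signed, mags = [], []
        for seed in range(5):
            cfg = nc.SimulationConfig(shared_fraction=0.0, seed=seed)
            rng = np.random.default_rng(seed)
            lat = nc.simulate_latent_signals(8, cfg, rng)
            hbo, _ = nc.simulate_fnirs_recording(lat, nc.default_montage(), cfg, rng)
            c = np.corrcoef(hbo.data)
            off = c[~np.eye(20, dtype=bool)]
            signed.append(off.mean())
            mags.append(np.abs(off).mean())
        assert abs(np.mean(signed)) < 0.05
        assert np.mean(mags) < 0.15

    def test_partial_sharing_orders_within_vs_between(self):
        """At shared_fraction 0.5, within-lobe r beats between-lobe r on average."""
        gaps = []
        for seed in range(20):
            cfg = nc.SimulationConfig(
                shared_fraction=0.5, duration_s=120.0, seed=seed, group_effect=None
            )
            rng = np.random.default_rng(seed)
            lat = nc.simulate_latent_signals(8, cfg, rng)
            layout = nc.default_montage()
            hbo, _ = nc.simulate_fnirs_recording(lat, layout, cfg, rng)
            c = np.corrcoef(hbo.data)
            groups = layout.channel_groups()
            within = []
            for members in groups.values():
                within += [c[i, j] for i in members for j in members if i < j]
            node = np.empty(20, int)
            for k, members in enumerate(groups.values()):
                node[members] = k
            between = [
                c[i, j] for i in range(20) for j in range(i + 1, 20) if node[i] != node[j]
            ]
            gaps.append(np.mean(within) - np.mean(between))
        assert np.mean(gaps) > 0.0
        assert np.mean(gaps) == pytest.approx(0.5, abs=0.15)

    def test_hbr_anticorrelated_with_hbo(self, fast_config, rng):
        lat = nc.simulate_latent_signals(8, fast_config, rng)
        hbo, hbr = nc.simulate_fnirs_recording(lat, nc.default_montage(), fast_config, rng)
        rs = [np.corrcoef(hbo.data[i], hbr.data[i])[0, 1] for i in range(20)]
        assert np.mean(rs) < -0.5

    def test_wrong_latent_dimension_rejected(self, fast_config, rng):
        with pytest.raises(DimensionError):
            nc.simulate_fnirs_recording(
                np.zeros((5, 100)), nc.default_montage(), fast_config, rng
            )


class TestFmriForwardModel:
    def test_exact_volume_count(self, fast_config, rng):
        lat = nc.simulate_latent_signals(8, fast_config, rng)
        bold = nc.simulate_fmri_recording(lat, fast_config, rng)
        assert bold.data.shape == (8, 35)
        assert bold.fs == pytest.approx(1.0 / 3.0)
        assert bold.modality == "BOLD"

    def test_noiseless_resampling_preserves_correlation_ordering(self):
        """With enough volumes, tiered latent correlations keep their ranks."""
        cfg = nc.SimulationConfig(
            rho_within=0.8, rho_between=0.3, rho_subject_sd=0.0,
            bold_noise_sd=0.0, n_volumes_fmri=100, seed=4,
        )
        rng = np.random.default_rng(4)
        lat = nc.simulate_latent_signals(8, cfg, rng)
        bold = nc.simulate_fmri_recording(lat, cfg, rng)
        c_lat = np.corrcoef(lat)
        c_bold = np.corrcoef(bold.data)
        iu = np.triu_indices(8, 1)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(c_lat[iu], c_bold[iu])
        assert rho > 0.9
        # the planted tiers (within 0.8 / between 0.3) stay separated
        within = [c_bold[i, j] for comm in cfg.communities for i in comm for j in comm if i < j]
        between = [c_bold[i, j] for i in cfg.communities[0] for j in cfg.communities[1]]
        assert min(within) > max(between) - 0.05

    def test_zero_latents_give_pure_noise(self, fast_config, rng):
        bold = nc.simulate_fmri_recording(
            np.zeros((8, fast_config.n_samples_fnirs)), fast_config, rng
        )
        hbo_lat = nc.simulate_latent_signals(8, fast_config, np.random.default_rng(0))
        # independent of any fNIRS-band structure: correlations with resampled
        # latents hover near zero
        t = np.arange(35) * 3.0
        resampled = np.vstack(
            [
                np.interp(t, np.arange(hbo_lat.shape[1]) / fast_config.fs_fnirs, row)
                for row in hbo_lat
            ]
        )
        cors = [np.corrcoef(bold.data[i], resampled[i])[0, 1] for i in range(8)]
        assert np.abs(np.mean(cors)) < 0.25

    def test_short_recording_rejected(self, fast_config, rng):
        with pytest.raises(DimensionError):
            nc.simulate_fmri_recording(np.zeros((8, 100)), fast_config, rng)


class TestCohort:
    def test_bit_identical_under_same_seed(self, fast_config):
        a = nc.simulate_cohort(fast_config)
        b = nc.simulate_cohort(fast_config)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            np.testing.assert_array_equal(sa.hbo.data, sb.hbo.data)
            np.testing.assert_array_equal(sa.bold.data, sb.bold.data)
            assert sa.gm_volume == sb.gm_volume

    def test_group_sizes_and_covariate_ranges(self, small_cohort, fast_config):
        groups = [s.group for s in small_cohort]
        assert groups.count("case") == fast_config.n_per_group
        assert groups.count("control") == fast_config.n_per_group
        for s in small_cohort:
            assert 36.0 <= s.ga_birth <= 42.0
            assert s.ga_birth <= s.pma_scan <= s.ga_birth + 2.0
            assert s.sex in ("M", "F")
            assert s.gm_volume > 0 and s.wm_volume > 0

    def test_null_effect_makes_groups_exchangeable(self):
        """With no planted effect both groups share community layout and rho."""
        cfg = nc.SimulationConfig(n_per_group=3, duration_s=120.0, group_effect=None, seed=0)
        subs = nc.simulate_cohort(cfg)
        assert all(s.communities == cfg.communities for s in subs)

    def test_planted_effect_raises_case_clustering(self):
        """Direction check: case clustering coefficient exceeds control on average."""
        diffs = []
        for seed in range(6):
            cfg = nc.SimulationConfig(n_per_group=4, duration_s=120.0, seed=seed)
            subs = nc.simulate_cohort(cfg)
            cps = {"case": [], "control": []}
            for s in subs:
                sp = nc.sparsify(nc.correlation_map(s.hbo), 0.3, binarized=True)
                cps[s.group].append(nc.clustering_coefficient(sp))
            diffs.append(np.mean(cps["case"]) - np.mean(cps["control"]))
        assert np.mean(diffs) > 0.0

    def test_zero_volume_link_keeps_volumes_independent(self):
        """volume_link = 0: the strength regression stays null in most reps."""
        hits = 0
        reps = 20
        for seed in range(reps):
            cfg = nc.SimulationConfig(
                n_per_group=5, duration_s=120.0, volume_link=0.0,
                group_effect=None, seed=seed,
            )
            subs = nc.simulate_cohort(cfg)
            strengths = [
                nc.total_connectivity_strength(
                    nc.correlation_map(nc.average_by_lobe(s.hbo))
                )
                for s in subs
            ]
            res = nc.covariate_adjusted_regression(
                cohort_frame(subs), strengths, "gm_volume"
            )
            hits += res.slope_p >= 0.05
        assert hits >= 0.9 * reps

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            nc.SimulationConfig(n_per_group=1)


def test_cohort_frame_columns(small_cohort):
    df = cohort_frame(small_cohort)
    assert list(df.columns) == [
        "subject_id", "group", "ga_birth", "pma_scan", "sex", "gm_volume", "wm_volume",
    ]
    assert len(df) == len(small_cohort)
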