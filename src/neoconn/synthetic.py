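"""Synthetic neonatal cohort generator.

A latent-lobe factor model: each of the 8 (hemisphere, lobe) nodes carries a
band-limited latent signal; lobes inside the same planted community share a
common factor (within-community correlation ``rho_within``, raised by the
planted group effect in cases). fNIRS channels load on their lobe latent with
weight ``sqrt(shared_fraction)`` plus independent band-limited noise; Hbr is
an anticorrelated copy of HbO; BOLD resamples the same latents at the fMRI
repetition time. Group differences, covariates and a configurable
volume-connectivity link are planted so every downstream stage can be tested
against known ground truth.

All randomness flows from one master seed through per-subject
``numpy.random.SeedSequence`` spawns, so cohorts are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import GroupEffect, SimulationConfig
from .connectivity import correlation_map, total_connectivity_strength
from .exceptions import ConfigurationError, DimensionError
from .montage import LOBE_NODE_ORDER, MontageLayout, default_montage
from .preprocess import average_by_lobe, bandpass_array
from .recording import TimeSeriesRecording


@dataclass
class SubjectRecord:
    """One synthetic neonate: group, covariates, volumes and recordings."""

    subject_id: str
    group: str  # "case" | "control"
    ga_birth: float  # weeks
    pma_scan: float  # weeks
    sex: str  # "M" | "F"
    gm_volume: float  # mm^3
    wm_volume: float  # mm^3
    hbo: Optional[TimeSeriesRecording] = None
    hbr: Optional[TimeSeriesRecording] = None
    bold: Optional[TimeSeriesRecording] = None
    communities: Optional[Tuple[Tuple[int, ...], ...]] = None

    def __post_init__(self):
        if self.group not in ("case", "control"):
            raise ConfigurationError(f"group must be case/control, got {self.group!r}")
        if self.pma_scan < self.ga_birth:
            raise ConfigurationError("pma_scan must be >= ga_birth")
        if self.gm_volume <= 0 or self.wm_volume <= 0:
            raise ConfigurationError("volumes must be positive")


def _band_noise(shape, rng: np.random.Generator, fs: float, band) -> np.ndarray:
    """Unit-variance Gaussian noise with support exactly inside ``band``.

    Synthesized in the frequency domain (random complex spectrum, zero
    outside the band), so the band limit is exact rather than a filter
    roll-off; rows are standardized to zero mean and unit variance.
    """
    if np.isscalar(shape) or isinstance(shape, tuple) and len(shape) == 1:
        shape = (1, shape[0] if isinstance(shape, tuple) else shape)
        squeeze = True
    else:
        squeeze = False
    rows, n = shape
    from scipy.fft import next_fast_len

    n_fft = next_fast_len(n, real=True)  # pad for FFT speed, then truncate
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    support = (freqs >= band[0]) & (freqs <= band[1])
    if not support.any():
        raise ConfigurationError(
            f"band {band} Hz contains no Fourier bin at n={n}, fs={fs}"
        )
    spec = np.zeros((rows, freqs.size), dtype=complex)
    k = int(support.sum())
    spec[:, support] = rng.standard_normal((rows, k)) + 1j * rng.standard_normal((rows, k))
    x = np.fft.irfft(spec, n=n_fft, axis=-1)[..., :n]
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    x /= sd
    return x[0] if squeeze else x


def simulate_latent_signals(
    n_lobes: int,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    rho_within: Optional[float] = None,
    communities: Optional[Sequence[Sequence[int]]] = None,
) -> np.ndarray:
    """Zero-mean, unit-variance, band-limited latent signals, one per lobe.

    Lobes in the same community correlate at ``rho_within``; lobes in
    different communities at ``rho_between``. Returns an (n_lobes, n_samples)
    matrix at the fNIRS sampling rate.
    """
    if n_lobes < 1:
        raise ConfigurationError("n_lobes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rho_w = config.rho_within if rho_within is None else rho_within
    rho_b = config.rho_between
    if not 0.0 <= rho_b <= rho_w <= 1.0:
        raise ConfigurationError(
            f"need 0 <= rho_between <= rho_within <= 1, got {rho_b}, {rho_w}"
        )
    if communities is None:
        if n_lobes == 8:
            communities = config.communities
        else:  # split in half for library use
            half = n_lobes // 2
            communities = (tuple(range(half)), tuple(range(half, n_lobes)))
    n = config.n_samples_fnirs
    fs, band = config.fs_fnirs, config.latent_band

    draws = _band_noise((1 + len(communities) + n_lobes, n), rng, fs, band)
    global_factor = draws[0]
    shared_factors = draws[1 : 1 + len(communities)]
    eps = draws[1 + len(communities) :]
    latents = np.empty((n_lobes, n))
    for shared, members in zip(shared_factors, communities):
        for m in members:
            if m >= n_lobes:
                continue
            latents[m] = (
                np.sqrt(rho_b) * global_factor
                + np.sqrt(rho_w - rho_b) * shared
                + np.sqrt(1.0 - rho_w) * eps[m]
            )
    # re-standardize: the factor mixture has unit variance only in expectation
    latents -= latents.mean(axis=-1, keepdims=True)
    latents /= latents.std(axis=-1, keepdims=True)
    return latents


def simulate_fnirs_recording(
    latents: np.ndarray,
    layout: MontageLayout,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "",
) -> Tuple[TimeSeriesRecording, TimeSeriesRecording]:
    """Forward model from lobe latents to 20-channel HbO and Hbr recordings.

    Each channel is ``sqrt(f) * latent + sqrt(1-f) * noise_sd * eta`` with
    ``f = shared_fraction`` and eta independent band-limited noise, so ``f``
    is exactly the latent-driven variance fraction at ``noise_sd = 1``.
    Hbr is ``-hbr_alpha * HbO`` plus independent noise.
    """
    latents = np.asarray(latents, float)
    if latents.shape[0] != len(LOBE_NODE_ORDER):
        raise DimensionError(
            f"latents must have {len(LOBE_NODE_ORDER)} rows, got {latents.shape[0]}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = layout.channel_groups()
    node_of_channel = np.empty(layout.n_channels, dtype=int)
    for node_idx, node in enumerate(LOBE_NODE_ORDER):
        for ch in groups[node]:
            node_of_channel[ch] = node_idx

    n = latents.shape[1]
    f = config.shared_fraction
    noise = _band_noise((layout.n_channels, n), rng, config.fs_fnirs, config.latent_band)
    hbo_data = (
        np.sqrt(f) * latents[node_of_channel]
        + np.sqrt(1.0 - f) * config.noise_sd * noise
    )
    hbr_noise = _band_noise(
        (layout.n_channels, n), rng, config.fs_fnirs, config.latent_band
    )
    hbr_data = -config.hbr_alpha * hbo_data + config.hbr_noise_sd * hbr_noise

    hbo = TimeSeriesRecording(
        hbo_data, config.fs_fnirs, "HbO", layout.channel_ids, layout, subject_id
    )
    hbr = TimeSeriesRecording(
        hbr_data, config.fs_fnirs, "Hbr", layout.channel_ids, layout, subject_id
    )
    return hbo, hbr


def simulate_fmri_recording(
    latents: np.ndarray,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "",
) -> TimeSeriesRecording:
    """Matched-modality BOLD: latents anti-alias filtered, sampled at TR.

    The latent band (<= 0.1 Hz) already sits below the fMRI Nyquist at
    TR = 3 s, so the anti-alias step is a no-op at the defaults; it matters
    only for wider configured bands. White noise of SD ``bold_noise_sd`` is
    added at the volume level.
    """
    latents = np.asarray(latents, float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.fs_fnirs
    n_vol, tr = config.n_volumes_fmri, config.tr_fmri
    needed = (n_vol - 1) * tr
    duration = (latents.shape[1] - 1) / fs
    if duration < needed:
        raise DimensionError(
            f"latents span {duration:.1f}s but {n_vol} volumes at TR={tr}s need {needed:.1f}s"
        )
    nyq_fmri = 0.5 / tr
    sig = latents
    if config.latent_band[1] > 0.95 * nyq_fmri:
        from scipy import signal as _sig

        sos = _sig.butter(4, 0.95 * nyq_fmri, btype="low", fs=fs, output="sos")
        sig = _sig.sosfiltfilt(sos, sig, axis=-1)
    t_fnirs = np.arange(latents.shape[1]) / fs
    t_fmri = np.arange(n_vol) * tr
    bold = np.vstack([np.interp(t_fmri, t_fnirs, row) for row in sig])
    bold = bold + config.bold_noise_sd * rng.standard_normal(bold.shape)
    return TimeSeriesRecording(
        bold, 1.0 / tr, "BOLD", LOBE_NODE_ORDER, layout=None, subject_id=subject_id
    )


def _random_communities(rng: np.random.Generator) -> Tuple[Tuple[int, ...], ...]:
    """A random 4+4 split of the 8 lobe nodes (case-subject community layout)."""
    perm = rng.permutation(8)
    return (tuple(sorted(perm[:4])), tuple(sorted(perm[4:])))


def _subject_rho(config: SimulationConfig, group: str, rng: np.random.Generator) -> float:
    rho = config.rho_within
    if group == "case" and config.group_effect is not None:
        rho += config.group_effect.magnitude
    rho += config.rho_subject_sd * rng.standard_normal()
    return float(np.clip(rho, config.rho_between, 0.97))


def simulate_subject(
    subject_id: str,
    group: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    layout: Optional[MontageLayout] = None,
) -> SubjectRecord:
    """One subject: latents -> HbO/Hbr/BOLD recordings + covariates (volumes filled later)."""
    layout = layout or default_montage()
    communities = config.communities
    if (
        group == "case"
        and config.group_effect is not None
        and config.group_effect.shuffle_communities
    ):
        communities = _random_communities(rng)
    rho = _subject_rho(config, group, rng)
    latents = simulate_latent_signals(8, config, rng, rho_within=rho, communities=communities)
    hbo, hbr = simulate_fnirs_recording(latents, layout, config, rng, subject_id)
    bold = simulate_fmri_recording(latents, config, rng, subject_id)

    ga = rng.uniform(*config.ga_range)
    pma = ga + rng.uniform(*config.scan_delay_range)
    sex = "M" if rng.random() < 0.5 else "F"
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        ga_birth=ga,
        pma_scan=pma,
        sex=sex,
        gm_volume=1.0,  # placeholder; linked to connectivity in simulate_cohort
        wm_volume=1.0,
        hbo=hbo,
        hbr=hbr,
        bold=bold,
        communities=communities,
    )


def simulate_cohort(config: SimulationConfig) -> List[SubjectRecord]:
    """Generate the full case/control cohort.

    Grey/white-matter volumes are linked to each subject's overall lobe-wise
    HbO connectivity strength with slope ``volume_link`` (mm^3 per cohort
    z-score of strength), so the volume-regression stage has recoverable
    ground truth; set ``volume_link = 0`` for independence.
    """
    if config.n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    layout = default_montage()
    master = np.random.SeedSequence(config.seed)
    n_total = 2 * config.n_per_group
    streams = master.spawn(n_total + 1)
    vol_rng = np.random.default_rng(streams[-1])

    subjects: List[SubjectRecord] = []
    for i in range(n_total):
        group = "case" if i < config.n_per_group else "control"
        sid = f"{'hie' if group == 'case' else 'ctl'}{(i % config.n_per_group) + 1:03d}"
        rng = np.random.default_rng(streams[i])
        subjects.append(simulate_subject(sid, group, config, rng, layout))

    # link volumes to overall HbO connectivity strength (lobe-wise map,
    # weighted, unfiltered), standardized across the cohort
    strengths = np.array(
        [
            total_connectivity_strength(correlation_map(average_by_lobe(s.hbo)))
            for s in subjects
        ]
    )
    sd = strengths.std()
    z = (strengths - strengths.mean()) / sd if sd > 0 else np.zeros_like(strengths)
    for s, zi in zip(subjects, z):
        s.gm_volume = float(
            max(
                config.gm_volume_mean
                + config.volume_link * zi
                + config.gm_volume_sd * vol_rng.standard_normal(),
                1.0,
            )
        )
        s.wm_volume = float(
            max(
                config.wm_volume_mean
                + config.volume_link * zi
                + config.wm_volume_sd * vol_rng.standard_normal(),
                1.0,
            )
        )
    return subjects


def simulate_regression_dataset(
    n: int,
    slope: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    covariate_effects: Tuple[float, float, float] = (0.2, 0.1, 0.3),
):
    """Covariates + standardized volumes + strengths from a known linear model.

    ``strength = slope * volume_z + b_ga * ga + b_pma * pma + b_sex * sex + noise``.
    Volumes are on a z-score scale here (synthetic, for slope-recovery tests);
    returns a pandas DataFrame with the cohort covariate columns plus
    ``strength``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    b_ga, b_pma, b_sex = covariate_effects
    ga = rng.uniform(36.0, 42.0, n)
    pma = ga + rng.uniform(0.0, 2.0, n)
    sex = (rng.random(n) < 0.5).astype(int)
    vol = rng.standard_normal(n)
    strength = slope * vol + b_ga * ga + b_pma * pma + b_sex * sex + noise_sd * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i + 1:03d}" for i in range(n)],
            "ga_birth": ga,
            "pma_scan": pma,
            "sex": np.where(sex == 1, "M", "F"),
            "gm_volume": vol,
            "wm_volume": vol,  # same synthetic predictor scale
            "strength": strength,
        }
    )


def cohort_frame(subjects: Sequence[SubjectRecord]):
    """Covariate table (one row per subject) as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "ga_birth": [s.ga_birth for s in subjects],
            "pma_scan": [s.pma_scan for s in subjects],
            "sex": [s.sex for s in subjects],
            "gm_volume": [s.gm_volume for s in subjects],
            "wm_volume": [s.wm_volume for s in subjects],
        }
    )
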