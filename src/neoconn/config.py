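"""Simulation configuration for the synthetic neonatal cohort.

Defaults mirror the study conditions: 20 fNIRS channels at 10.1725 Hz for
6 min, BOLD at TR = 3 s with 35 volumes, latent lobe signals band-limited to
0.01-0.1 Hz, and a cohort of 20 cases + 20 controls.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class GroupEffect:
    """What is planted differently in the case group.

    ``within_community_coupling`` raises the case group's within-community
    latent correlation by ``magnitude`` and, when ``shuffle_communities`` is
    set, re-draws each case subject's lobe-community assignment at random.
    The coupling increase drives case > control clustering coefficient,
    local efficiency and modularity; the per-subject shuffling drives the
    lower within-group partition consistency of cases.
    """

    kind: str = "within_community_coupling"
    magnitude: float = 0.3
    shuffle_communities: bool = True

    def __post_init__(self):
        if self.kind not in ("within_community_coupling",):
            raise ConfigurationError(f"unknown group effect kind {self.kind!r}")
        if not -1.0 <= self.magnitude <= 1.0:
            raise ConfigurationError("group effect magnitude must be in [-1, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_per_group
        Subjects per group (cases and controls).
    duration_s, fs_fnirs
        fNIRS recording length (s) and sampling rate (Hz).
    tr_fmri, n_volumes_fmri
        BOLD repetition time (s) and number of volumes.
    latent_band
        Pass band (Hz) of the latent lobe signals.
    shared_fraction
        Fraction of each channel's variance driven by its lobe latent
        (exactly the variance fraction when ``noise_sd`` is 1).
    rho_within, rho_between
        Latent correlation between lobes inside / across the two planted
        communities (control group; cases add ``group_effect.magnitude``).
    rho_subject_sd
        Between-subject jitter (SD) on the within-community correlation, so
        subjects differ beyond correlation-estimator noise.
    group_effect
        Planted case-group difference, or ``None`` for a null cohort.
    noise_sd
        SD of the independent per-channel noise.
    hbr_alpha, hbr_noise_sd
        Hbr = -hbr_alpha * HbO + noise(hbr_noise_sd): the physiological
        HbO/Hbr anticorrelation.
    bold_noise_sd
        SD of white noise added to the resampled BOLD series.
    """

    n_per_group: int = 20
    duration_s: float = 360.0
    fs_fnirs: float = 10.1725
    tr_fmri: float = 3.0
    n_volumes_fmri: int = 35
    latent_band: Tuple[float, float] = (0.01, 0.1)
    shared_fraction: float = 0.6
    rho_within: float = 0.3
    rho_between: float = 0.1
    rho_subject_sd: float = 0.1
    communities: Tuple[Tuple[int, ...], ...] = ((0, 1, 2, 3), (4, 5, 6, 7))
    group_effect: Optional[GroupEffect] = GroupEffect()
    noise_sd: float = 1.0
    hbr_alpha: float = 0.5
    hbr_noise_sd: float = 0.3
    bold_noise_sd: float = 0.5
    # covariate distributions: term neonates, GA uniform 36-42 wk,
    # scan within 2 wk of birth, volumes in mm^3
    ga_range: Tuple[float, float] = (36.0, 42.0)
    scan_delay_range: Tuple[float, float] = (0.0, 2.0)
    gm_volume_mean: float = 220_000.0
    gm_volume_sd: float = 25_000.0
    wm_volume_mean: float = 180_000.0
    wm_volume_sd: float = 20_000.0
    volume_link: float = 10_000.0  # mm^3 per unit z-score of HbO strength
    seed: int = 0

    def __post_init__(self):
        low, high = self.latent_band
        if not 0 < low < high:
            raise ConfigurationError(f"invalid latent band {self.latent_band}")
        if high > self.fs_fnirs / 2:
            raise ConfigurationError(
                f"latent band upper edge {high} Hz exceeds Nyquist {self.fs_fnirs / 2} Hz"
            )
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be at least 2")
        if self.duration_s * self.fs_fnirs < 2:
            raise ConfigurationError("recording must span at least 2 samples")
        if self.n_volumes_fmri * self.tr_fmri > self.duration_s:
            raise ConfigurationError(
                "fMRI run longer than the simulated recording: "
                f"{self.n_volumes_fmri} volumes x {self.tr_fmri} s > {self.duration_s} s"
            )
        flat = [i for c in self.communities for i in c]
        if sorted(flat) != list(range(8)):
            raise ConfigurationError("communities must partition the 8 lobe nodes")

    @property
    def n_samples_fnirs(self) -> int:
        return int(round(self.duration_s * self.fs_fnirs))
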