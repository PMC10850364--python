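"""In-memory container for multi-channel hemodynamic time series."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import DimensionError, FormatError
from .montage import MontageLayout

MODALITIES = ("OD", "HbO", "Hbr", "BOLD")

#: the two operating wavelengths of the optical system, nm
WAVELENGTHS = (760.0, 850.0)


@dataclass
class TimeSeriesRecording:
    """A channel x time matrix with sampling metadata.

    For ``modality="OD"`` the data carry one plane per wavelength and have
    shape ``(2, n_channels, n_times)`` (planes ordered 760 nm, 850 nm); all
    other modalities are 2-D ``(n_channels, n_times)``. HbO/Hbr are
    concentration changes in uM; OD and BOLD are in arbitrary units.
    """

    data: np.ndarray
    fs: float
    modality: str
    channel_names: Tuple[str, ...]
    layout: Optional[MontageLayout] = None
    subject_id: str = ""
    wavelengths: Tuple[float, float] = WAVELENGTHS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}")
        if self.fs <= 0:
            raise DimensionError(f"sampling rate must be positive, got {self.fs}")
        if self.modality == "OD":
            if self.data.ndim != 3 or self.data.shape[0] != 2:
                raise FormatError(
                    "OD recordings need two wavelength planes: shape (2, channels, times)"
                )
        elif self.data.ndim != 2:
            raise DimensionError(
                f"{self.modality} data must be 2-D (channels, times), got {self.data.ndim}-D"
            )
        if self.n_channels != len(self.channel_names):
            raise DimensionError(
                f"{self.n_channels} data rows but {len(self.channel_names)} channel names"
            )
        if self.layout is not None and self.layout.n_channels != self.n_channels:
            raise DimensionError("layout channel count does not match data")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[-2]

    @property
    def n_times(self) -> int:
        return self.data.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def with_data(self, data: np.ndarray, modality: Optional[str] = None) -> "TimeSeriesRecording":
        """Copy of this recording with new samples (and optionally modality)."""
        return replace(self, data=data, modality=modality or self.modality)
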