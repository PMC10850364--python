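"""Signal preprocessing: MBLL conversion, band-pass filtering, lobe averaging.

The modified Beer-Lambert law (MBLL) converts optical-density changes at the
two operating wavelengths into oxy-/deoxy-hemoglobin concentration changes by
solving, per channel and sample, the 2x2 linear system

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_Hbr(lambda) dHbr] * d * DPF(lambda)

where ``eps`` are molar extinction coefficients (cm^-1 M^-1), ``d`` the
source-detector distance (cm) and ``DPF`` the differential pathlength factor.
Band-pass filtering is zero-phase (forward-backward Butterworth), so it adds
no group delay and leaves Pearson correlations phase-neutral.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, FormatError, LayoutError
from .montage import LOBE_NODE_ORDER
from .recording import TimeSeriesRecording

logger = logging.getLogger(__name__)

# Default molar extinction coefficients, cm^-1 M^-1 (Prahl-type compiled
# values at 760 and 850 nm) and neonatal-head DPF conventions. These are
# standard-table conventions, configurable via MbllParameters.
DEFAULT_EXTINCTION = np.array(
    [
        # [eps_HbO, eps_Hbr]
        [586.0, 1548.52],  # 760 nm
        [1058.0, 691.32],  # 850 nm
    ]
)
DEFAULT_DPF = (5.0, 4.4)  # 760 nm, 850 nm
DEFAULT_SD_DISTANCE_CM = 2.5


@dataclass(frozen=True)
class MbllParameters:
    """Constants of the MBLL 2x2 system.

    ``extinction[w, s]`` is the molar extinction coefficient of species
    ``s in (HbO, Hbr)`` at wavelength ``w in (760, 850) nm``.
    """

    extinction: np.ndarray = None
    dpf: Tuple[float, float] = DEFAULT_DPF
    sd_distance: float = DEFAULT_SD_DISTANCE_CM

    def __post_init__(self):
        ext = DEFAULT_EXTINCTION if self.extinction is None else np.asarray(self.extinction, float)
        object.__setattr__(self, "extinction", ext)
        if ext.shape != (2, 2):
            raise ConfigurationError("extinction must be a 2x2 matrix (wavelength x species)")
        if abs(np.linalg.det(ext)) < 1e-12 * np.abs(ext).max() ** 2:
            raise ConfigurationError("extinction matrix is singular; MBLL system unsolvable")
        if any(d <= 0 for d in self.dpf):
            raise ConfigurationError("DPF values must be positive")
        if self.sd_distance <= 0:
            raise ConfigurationError("source-detector distance must be positive")

    def system_matrix(self) -> np.ndarray:
        """The 2x2 matrix mapping (dHbO, dHbr) to (dOD_760, dOD_850)."""
        dpf = np.asarray(self.dpf, float)
        return self.extinction * self.sd_distance * dpf[:, None]


def mbll_forward(hbo: np.ndarray, hbr: np.ndarray, params: MbllParameters) -> np.ndarray:
    """Forward MBLL model: concentrations -> OD planes, shape (2, channels, times)."""
    conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)])  # (2, C, T)
    m = params.system_matrix()
    return np.einsum("ws,sct->wct", m, conc)


def mbll_convert(
    od: TimeSeriesRecording, params: MbllParameters | None = None
) -> Tuple[TimeSeriesRecording, TimeSeriesRecording]:
    """Invert the MBLL system per channel and sample.

    Returns HbO and Hbr recordings sharing the input's sampling rate and
    layout. Units follow the extinction coefficients: with the default molar
    table the outputs are molar concentration changes.
    """
    if params is None:
        params = MbllParameters()
    if od.modality != "OD":
        raise FormatError(f"mbll_convert needs an OD recording, got {od.modality}")
    m = params.system_matrix()
    flat = od.data.reshape(2, -1)  # (2, C*T)
    conc = np.linalg.solve(m, flat).reshape(od.data.shape)
    hbo = TimeSeriesRecording(
        conc[0], od.fs, "HbO", od.channel_names, od.layout, od.subject_id
    )
    hbr = TimeSeriesRecording(
        conc[1], od.fs, "Hbr", od.channel_names, od.layout, od.subject_id
    )
    return hbo, hbr


def design_bandpass(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the zero-phase band-pass (applied via sosfiltfilt)."""
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ConfigurationError(f"invalid band [{low}, {high}] Hz")
    if high >= nyq:
        raise ConfigurationError(
            f"band upper edge {high} Hz not below Nyquist {nyq} Hz at fs={fs}"
        )
    return signal.butter(order, [low, high], btype="band", fs=fs, output="sos")


def clamp_band(low: float, high: float, fs: float) -> Tuple[float, float]:
    """Clamp the upper band edge to 0.95 x Nyquist when the rate cannot carry it.

    The BOLD filter setting (0.01-0.2 Hz) exceeds the Nyquist frequency at
    TR = 3 s; rather than failing, the band is narrowed to what the sampling
    rate physically supports, with a logged warning.
    """
    nyq = fs / 2.0
    if high >= nyq:
        clamped = 0.95 * nyq
        logger.warning(
            "band edge %.4g Hz exceeds Nyquist %.4g Hz at fs=%.4g; clamping to %.4g Hz",
            high, nyq, fs, clamped,
        )
        high = clamped
    if not 0 < low < high:
        raise ConfigurationError(f"band [{low}, {high}] Hz infeasible at fs={fs}")
    return low, high


def bandpass_array(
    data: np.ndarray, fs: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = design_bandpass(low, high, fs, order)
    return signal.sosfiltfilt(sos, np.asarray(data, float), axis=-1)


def bandpass_filter(
    rec: TimeSeriesRecording, low: float, high: float, order: int = 4, clamp: bool = False
) -> TimeSeriesRecording:
    """Band-pass a recording without changing its length or phase.

    With ``clamp=True`` an upper edge at or above Nyquist is narrowed via
    :func:`clamp_band` instead of raising.
    """
    if clamp:
        low, high = clamp_band(low, high, rec.fs)
    return rec.with_data(bandpass_array(rec.data, rec.fs, low, high, order))


def average_by_lobe(rec: TimeSeriesRecording) -> TimeSeriesRecording:
    """Average channels into the 8 canonical (hemisphere, lobe) nodes.

    Each output row is the unweighted mean of its member channels; the output
    node order is :data:`~neoconn.montage.LOBE_NODE_ORDER`, shared with the
    fMRI lobe maps.
    """
    if rec.layout is None:
        raise LayoutError("recording has no montage layout; cannot lobe-average")
    if rec.modality == "OD":
        raise FormatError("convert OD to HbO/Hbr before lobe averaging")
    groups = rec.layout.channel_groups()
    out = np.empty((len(LOBE_NODE_ORDER), rec.n_times))
    for i, node in enumerate(LOBE_NODE_ORDER):
        out[i] = rec.data[groups[node]].mean(axis=0)
    return TimeSeriesRecording(
        out, rec.fs, rec.modality, LOBE_NODE_ORDER, layout=None, subject_id=rec.subject_id
    )
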