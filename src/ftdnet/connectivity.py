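"""Quality control and wavelet-band connectivity estimation.

Subjects whose fMRI series contain too many motion spikes are excluded on a
scalar spike-percentage threshold (default 10%, strict inequality).  For the
survivors, region-by-region connectivity is the Pearson correlation of
maximal-overlap wavelet detail coefficients at a single dyadic frequency
scale, the scale whose passband best overlaps a target band (default
0.0675-0.125 Hz).  The transform is the stationary (maximal-overlap) discrete
wavelet transform with Daubechies-4 filters and reflection boundary handling;
boundary-affected coefficients are discarded before correlating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "ParcellatedTimeSeries",
    "WaveletBand",
    "ConnectivityMatrix",
    "exclude_by_spike_pct",
    "select_wavelet_scale",
    "wavelet_detail_coefficients",
    "wavelet_correlation_matrix",
]

DEFAULT_TARGET_BAND = (0.0675, 0.125)
DEFAULT_WAVELET = "db4"


@dataclass
class ParcellatedTimeSeries:
    """A subject's region x time signal matrix with its sampling interval."""

    subject_id: str
    signal: np.ndarray  # shape (n_regions, n_timepoints)
    tr_seconds: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D region x time matrix")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"non-finite values in time series of {self.subject_id}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class WaveletBand:
    """One dyadic wavelet scale and the frequency band it covers.

    Scale ``j`` of a non-decimated dyadic transform on a signal sampled at
    ``fs`` covers (nominally) ``[fs / 2**(j+1), fs / 2**j]`` Hz.
    """

    scale_index: int
    f_low: float
    f_high: float
    wavelet_family: str = DEFAULT_WAVELET

    def __post_init__(self) -> None:
        if self.scale_index < 1:
            raise ValueError("scale_index must be >= 1")
        if not (0 < self.f_low < self.f_high):
            raise ValueError("require 0 < f_low < f_high")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric unit-diagonal wavelet cross-correlation matrix."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def exclude_by_spike_pct(subjects, threshold_pct: float = 10.0):
    """Partition subjects by motion-spike percentage.

    A subject is excluded iff ``spike_pct`` is strictly greater than the
    threshold; the retained/excluded lists partition the input exactly.
    """
    retained, excluded = [], []
    for s in subjects:
        spike = getattr(s, "spike_pct", None)
        if spike is None or (isinstance(spike, float) and np.isnan(spike)):
            raise ValueError(f"subject {getattr(s, 'subject_id', s)!r} has no spike_pct")
        (excluded if spike > threshold_pct else retained).append(s)
    return retained, excluded


def dyadic_band(tr_seconds: float, scale_index: int) -> tuple[float, float]:
    """Nominal passband of dyadic scale ``scale_index`` at sampling interval tr."""
    fs = 1.0 / tr_seconds
    return fs / 2 ** (scale_index + 1), fs / 2**scale_index


def select_wavelet_scale(
    tr_seconds: float,
    target_band: tuple[float, float] = DEFAULT_TARGET_BAND,
    wavelet_family: str = DEFAULT_WAVELET,
    max_scale: int = 10,
) -> WaveletBand:
    """Pick the dyadic scale with maximal frequency overlap with a target band.

    The target band (default 0.0675-0.125 Hz) rarely coincides with a dyadic
    band exactly, because repetition times vary across scanners; the scale is
    therefore chosen by overlap length rather than hard-coded.
    """
    f_lo, f_hi = target_band
    if not (0 < f_lo < f_hi):
        raise ValueError("target band must satisfy 0 < f_low < f_high")
    nyquist = 0.5 / tr_seconds
    if f_lo >= nyquist:
        raise ValueError(
            f"target band ({f_lo}-{f_hi} Hz) lies above the Nyquist frequency "
            f"{nyquist:.4f} Hz for tr={tr_seconds} s"
        )
    best, best_overlap = None, -1.0
    for j in range(1, max_scale + 1):
        lo, hi = dyadic_band(tr_seconds, j)
        overlap = max(0.0, min(hi, f_hi) - max(lo, f_lo))
        if overlap > best_overlap:
            best, best_overlap = j, overlap
    lo, hi = dyadic_band(tr_seconds, best)
    return WaveletBand(scale_index=best, f_low=lo, f_high=hi, wavelet_family=wavelet_family)


def _boundary_width(wavelet_family: str, level: int) -> int:
    filt_len = pywt.Wavelet(wavelet_family).dec_len
    return (2**level - 1) * (filt_len - 1)


def wavelet_detail_coefficients(signal: np.ndarray, band: WaveletBand) -> np.ndarray:
    """Boundary-trimmed non-decimated wavelet detail coefficients at one scale.

    The stationary wavelet transform requires a length that is a multiple of
    2**level; the signal is reflection-extended to the next multiple, and the
    filter-width-dependent edge coefficients are dropped from both ends.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n = x.shape[-1]
    level = band.scale_index
    b = _boundary_width(band.wavelet_family, level)
    if n < 2 ** (level + 1):
        raise ValueError(
            f"time series of length {n} too short for wavelet scale {level} "
            f"(need at least {2 ** (level + 1)} samples)"
        )
    pad = (-n) % (2**level)
    if pad:
        x = np.concatenate([x, x[..., ::-1][..., :pad]], axis=-1)
    coeffs = pywt.swt(x, band.wavelet_family, level=level, trim_approx=True, norm=True, axis=-1)
    detail = coeffs[1][..., :n]  # detail at the deepest (selected) level
    if n - 2 * b >= 16:
        detail = detail[..., b : n - b]
    elif n - b >= 16:  # short series: trim the start only
        detail = detail[..., b:]
    return detail


def wavelet_correlation_matrix(ts: ParcellatedTimeSeries, band: WaveletBand) -> ConnectivityMatrix:
    """Wavelet cross-correlation connectivity for one subject.

    Pearson correlation of the scale-``j`` detail coefficients for every
    region pair; symmetric with unit diagonal.  Constant (zero-variance)
    region signals make the correlation undefined and raise an error naming
    the offending regions rather than silently producing NaN.
    """
    nyquist = 0.5 / ts.tr_seconds
    if band.f_low >= nyquist:
        raise ValueError("wavelet band lies above the Nyquist frequency for this series")
    detail = wavelet_detail_coefficients(ts.signal, band)
    sd = detail.std(axis=-1)
    degenerate = np.flatnonzero(sd <= 1e-14)
    if degenerate.size:
        raise ValueError(
            f"zero-variance wavelet coefficients for regions {degenerate.tolist()} "
            f"of subject {ts.subject_id}; correlation undefined"
        )
    corr = np.corrcoef(detail)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, values=corr)
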