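"""Time-domain, spectral and Poincaré HRV features.

Conventions
-----------
* Population (not sample) variances throughout, so the algebraic
  identities between the descriptors hold exactly:

      RMSSD = sqrt(2) * SD1
      SDNN^2 = (SD1^2 + SD2^2) / 2

* Spectral bands: LF = [0.04, 0.15) Hz, HF = [0.15, 0.40] Hz.  Very-low
  frequency power is not analysed (short 5–10 min recordings).
* Normalised units are defined over LF + HF:  LF(nu) = 100 LF/(LF+HF),
  so LF(nu) + HF(nu) = 100 exactly.
* Spectra are estimated on the RR tachogram — the interval series
  cubic-spline resampled at 4 Hz and linearly detrended — by either a
  Hann-windowed Welch periodogram (150 s segments, 50% overlap) or a
  Burg autoregressive model (default order 16).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "SpectralMethod",
    "Tachogram",
    "SpectralEstimate",
    "HRVFeatures",
    "InsufficientDataError",
    "LF_BAND_HZ",
    "HF_BAND_HZ",
    "time_domain",
    "poincare",
    "resample_tachogram",
    "welch_psd",
    "ar_psd",
    "band_powers",
    "extract_features",
    "FEATURE_COLUMNS",
]

LF_BAND_HZ = (0.04, 0.15)
HF_BAND_HZ = (0.15, 0.40)

#: Canonical column order for feature tables.
FEATURE_COLUMNS = [
    "mean_rr_ms",
    "sdnn_ms",
    "rmssd_ms",
    "lf_power_ms2",
    "hf_power_ms2",
    "lf_nu",
    "hf_nu",
    "lf_hf",
    "lf_peak_hz",
    "hf_peak_hz",
    "sd1_ms",
    "sd2_ms",
    "sd2_sd1",
]


class InsufficientDataError(ValueError):
    pass


class SpectralMethod(str, enum.Enum):
    WELCH = "welch"
    AR_BURG = "ar_burg"


@dataclass(frozen=True)
class Tachogram:
    """Uniformly resampled RR series (ms) ready for spectral analysis."""

    fs_hz: float
    values_ms: np.ndarray
    detrend: str = "linear"

    def __post_init__(self):
        if self.fs_hz <= 2 * HF_BAND_HZ[1]:
            raise ValueError(
                f"fs_hz must exceed {2 * HF_BAND_HZ[1]} Hz (Nyquist above the HF band)"
            )
        object.__setattr__(self, "values_ms", np.asarray(self.values_ms, dtype=float))


@dataclass(frozen=True)
class SpectralEstimate:
    freq_hz: np.ndarray
    psd_ms2_per_hz: np.ndarray
    method: SpectralMethod
    params: dict


@dataclass(frozen=True)
class HRVFeatures:
    mean_rr_ms: float
    sdnn_ms: float
    rmssd_ms: float
    lf_power_ms2: float
    hf_power_ms2: float
    lf_nu: float
    hf_nu: float
    lf_hf: float
    lf_peak_hz: float
    hf_peak_hz: float
    sd1_ms: float
    sd2_ms: float
    sd2_sd1: float
    method: str = "welch"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS} | {"method": self.method}


def _check_rr(rr_ms, min_len: int, what: str) -> np.ndarray:
    rr = np.asarray(rr_ms, dtype=float)
    if rr.ndim != 1 or rr.size < min_len:
        raise InsufficientDataError(f"{what} requires at least {min_len} intervals")
    return rr


def time_domain(rr_ms) -> tuple[float, float, float]:
    """SDNN, RMSSD and mean RR (all ms).

    SDNN is the population standard deviation of the intervals; RMSSD the
    root mean square of successive differences.
    """
    rr = _check_rr(rr_ms, 2, "time_domain")
    sdnn = float(np.std(rr))
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    return sdnn, rmssd, float(np.mean(rr))


def poincare(rr_ms) -> tuple[float, float, float]:
    """Poincaré-plot descriptors SD1, SD2 and their ratio SD2/SD1.

    SD1 is the dispersion of (RR_n, RR_{n+1}) points perpendicular to the
    line of identity (short-term variability), SD2 the dispersion along
    it (long-term variability):

        SD1^2 = mean(diff RR ^ 2) / 2
        SD2^2 = 2 var(RR) - mean(diff RR ^ 2) / 2

    The successive-difference moment is uncentered, which makes
    ``RMSSD = sqrt(2) SD1`` an exact identity (the mean successive
    difference of a stationary series is ~0, so this matches the
    centred convention in practice).  The ratio is NaN (not an error)
    when SD1 = 0.
    """
    rr = _check_rr(rr_ms, 3, "poincare")
    var_d = float(np.mean(np.diff(rr) ** 2))
    var_rr = float(np.var(rr))
    sd1 = np.sqrt(0.5 * var_d)
    sd2 = np.sqrt(max(2.0 * var_rr - 0.5 * var_d, 0.0))
    ratio = sd2 / sd1 if sd1 > 0 else float("nan")
    return float(sd1), float(sd2), float(ratio)


def resample_tachogram(
    rr_ms,
    beat_times_s=None,
    fs_hz: float = 4.0,
    detrend: str = "linear",
) -> Tachogram:
    """Cubic-spline resample the RR series onto a uniform grid.

    Each interval is anchored at its ending beat time; when beat times
    are not supplied they are reconstructed as the cumulative sum of the
    intervals.  Optional linear detrending removes slow drift before
    spectral estimation.
    """
    rr = _check_rr(rr_ms, 2, "resample_tachogram")
    if detrend not in ("none", "linear"):
        raise ValueError("detrend must be 'none' or 'linear'")
    if beat_times_s is None:
        t = np.cumsum(rr) / 1000.0
    else:
        t = np.asarray(beat_times_s, dtype=float)
        if t.size == rr.size + 1:  # beat instants: interval i ends at beat i+1
            t = t[1:]
        elif t.size != rr.size:
            raise ValueError("beat_times_s incompatible with rr_ms")
    grid = np.arange(t[0], t[-1], 1.0 / fs_hz)
    values = CubicSpline(t, rr)(grid)
    if detrend == "linear" and values.size > 2:
        values = sps.detrend(values, type="linear")
    return Tachogram(fs_hz=float(fs_hz), values_ms=values, detrend=detrend)


def welch_psd(
    tach: Tachogram, window_s: float = 150.0, overlap: float = 0.5
) -> SpectralEstimate:
    """Hann-windowed Welch periodogram of the tachogram.

    Density-scaled so the integral over [0, fs/2] recovers the tachogram
    variance (Parseval contract).
    """
    x = tach.values_ms
    nperseg = int(round(window_s * tach.fs_hz))
    if x.size < nperseg:
        nperseg = x.size
    if x.size < 8:
        raise InsufficientDataError("welch_psd requires at least 8 tachogram samples")
    f, p = sps.welch(
        x - np.mean(x),
        fs=tach.fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend=False,
        scaling="density",
    )
    return SpectralEstimate(
        freq_hz=f,
        psd_ms2_per_hz=p,
        method=SpectralMethod.WELCH,
        params={"window_s": window_s, "overlap_fraction": overlap},
    )


def ar_psd(tach: Tachogram, order: int = 16, n_freq: int = 1024) -> SpectralEstimate:
    """Autoregressive (Burg) spectral estimate.

    Burg-recursion AR coefficients (via statsmodels) define the one-sided
    density  2 sigma^2 / fs / |1 - sum a_k exp(-i w k)|^2  on a dense
    grid over [0, fs/2]; order 0 degenerates to the flat white-noise
    spectrum at the sample-variance level.
    """
    x = tach.values_ms - np.mean(tach.values_ms)
    if order < 0:
        raise ValueError("order must be non-negative")
    if order >= x.size:
        raise ValueError("order must be smaller than the tachogram length")
    f = np.linspace(0.0, tach.fs_hz / 2.0, n_freq)
    if order == 0:
        sigma2 = float(np.var(x))
        p = np.full_like(f, 2.0 * sigma2 / tach.fs_hz)
    else:
        from statsmodels.regression.linear_model import burg

        ar, sigma2 = burg(x, order=order, demean=False)
        w = 2.0 * np.pi * f / tach.fs_hz
        denom = np.abs(
            1.0 - np.exp(-1j * np.outer(w, np.arange(1, order + 1))) @ ar
        ) ** 2
        p = 2.0 * sigma2 / tach.fs_hz / denom
    return SpectralEstimate(
        freq_hz=f,
        psd_ms2_per_hz=p,
        method=SpectralMethod.AR_BURG,
        params={"ar_order": order},
    )


def _band_integral(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over [lo, hi], with the band
    edges inserted by linear interpolation."""
    if hi <= f[0] or lo >= f[-1]:
        return 0.0
    lo = max(lo, f[0])
    hi = min(hi, f[-1])
    inside = (f > lo) & (f < hi)
    fb = np.concatenate(([lo], f[inside], [hi]))
    pb = np.concatenate(([np.interp(lo, f, p)], p[inside], [np.interp(hi, f, p)]))
    return float(np.trapezoid(pb, fb))


def band_powers(spec: SpectralEstimate) -> dict:
    """Integrate the spectrum over the LF and HF bands.

    Returns absolute powers (ms^2), normalised units over LF+HF, the
    LF/HF ratio, and the in-band peak frequencies.  When LF+HF = 0 the
    normalised quantities and the ratio are NaN sentinels.
    """
    f, p = spec.freq_hz, spec.psd_ms2_per_hz
    lf = _band_integral(f, p, *LF_BAND_HZ)
    hf = _band_integral(f, p, *HF_BAND_HZ)
    total = lf + hf
    if total > 0:
        lf_nu = 100.0 * lf / total
        hf_nu = 100.0 * hf / total
    else:
        lf_nu = hf_nu = float("nan")
    lf_hf = lf / hf if hf > 0 else float("nan")

    def _peak(lo, hi):
        mask = (f >= lo) & (f <= hi)
        if not np.any(mask) or np.all(p[mask] == 0):
            return float("nan")
        return float(f[mask][np.argmax(p[mask])])

    return {
        "lf_power_ms2": lf,
        "hf_power_ms2": hf,
        "lf_nu": lf_nu,
        "hf_nu": hf_nu,
        "lf_hf": lf_hf,
        "lf_peak_hz": _peak(*LF_BAND_HZ),
        "hf_peak_hz": _peak(*HF_BAND_HZ),
    }


def extract_features(
    rr_ms,
    beat_times_s=None,
    method: SpectralMethod | str = SpectralMethod.WELCH,
    fs_hz: float = 4.0,
    min_beats: int = 64,
) -> HRVFeatures:
    """Compute the full HRV feature record for one RR series."""
    method = SpectralMethod(method)
    rr = _check_rr(rr_ms, min_beats, "extract_features")
    sdnn, rmssd, mean_rr = time_domain(rr)
    sd1, sd2, ratio = poincare(rr)
    tach = resample_tachogram(rr, beat_times_s=beat_times_s, fs_hz=fs_hz)
    spec = welch_psd(tach) if method is SpectralMethod.WELCH else ar_psd(tach)
    bands = band_powers(spec)
    return HRVFeatures(
        mean_rr_ms=mean_rr,
        sdnn_ms=sdnn,
        rmssd_ms=rmssd,
        sd1_ms=sd1,
        sd2_ms=sd2,
        sd2_sd1=ratio,
        method=method.value,
        **bands,
    )
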