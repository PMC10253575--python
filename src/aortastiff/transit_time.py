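"""Transit-time estimation between aortic flow-rate curves.

Three estimators of the delay between the waveform's arrival at two
locations along the aorta:

``wavelet_delay``
    Cross-wavelet phase method.  Both curves are transformed with an
    analytic Morlet wavelet; within a time-frequency region restricted to
    the systolic upslope of the first curve and to scales where both
    transforms carry energy, the cross-spectrum phase at each scale is
    converted to a delay and averaged with weights proportional to
    cross-spectral amplitude times frequency squared (phase noise maps to
    delay error as 1/f, so higher-frequency scales are more informative).
    This is the estimator of choice at the coarse temporal resolution of
    4D-flow MRI.

``foot_delay``
    Classical intersecting-tangent foot-to-foot method: the foot of each
    curve is the intersection of the pre-upslope baseline with the tangent
    at maximal upslope.

``upslope_xcorr_delay``
    Normalized cross-correlation of the systolic upslope segments on a
    band-limited fine grid, with parabolic sub-sample refinement of the
    correlation peak.  Used for the two-plane (2D) transit time.

All estimators treat curves as periodic over one cardiac cycle and report
the delay of the second curve relative to the first (positive when the
second lags).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import (InsufficientDataError, InvalidArgumentError,
                     LowQualityError, NoSignalError)
from .synthetic import FlowCurveSet

__all__ = [
    "TransitTimeResult",
    "wavelet_delay",
    "foot_delay",
    "upslope_xcorr_delay",
    "plane_delays",
]

# Morlet with center-frequency parameter ~6 (fc = 6/2pi), bandwidth 1.5
_WAVELET = "cmor1.5-0.9549"
_FMIN, _FMAX, _N_SCALES = 1.0, 12.0, 32
_XCORR_FINE_DT = 0.002   # s, internal correlation grid
_XCORR_F_CUT = 8.0       # Hz, band limit of the internal resampler
_XCORR_MIN_PEAK = 0.5    # minimum admissible correlation peak


@dataclass(frozen=True)
class TransitTimeResult:
    """Per-plane delays of the reference waveform relative to each plane.

    ``delays[i]`` is positive when plane ``i`` is upstream of the reference
    (the wave arrives at the plane first); the entry at the reference plane
    is exactly 0.  Planes whose estimate failed the quality gate carry NaN.
    """

    reference_index: int
    delays: np.ndarray    # (n_planes,) s, NaN = missing
    quality: np.ndarray   # (n_planes,) in [0, 1]
    method: str

    def __post_init__(self) -> None:
        if self.delays[self.reference_index] != 0.0:
            raise InvalidArgumentError("reference-plane delay must be 0")
        q = self.quality[np.isfinite(self.quality)]
        if q.size and (q.min() < 0 or q.max() > 1):
            raise InvalidArgumentError("quality must be in [0, 1]")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.delays).sum())


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _check_pair(qa, qb, time_axis):
    qa = np.asarray(qa, float)
    qb = np.asarray(qb, float)
    t = np.asarray(time_axis, float)
    if qa.shape != t.shape or qb.shape != t.shape:
        raise InvalidArgumentError("curves and time axis must have equal length")
    if t.size < 8:
        raise InvalidArgumentError("need at least 8 samples per cycle")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise InvalidArgumentError("time axis must be uniformly sampled")
    if np.ptp(qa) == 0 or np.ptp(qb) == 0:
        raise NoSignalError("flat (zero-variance) flow curve")
    return qa, qb, t, float(dt[0])


def _upslope_mask(q: np.ndarray, dilate: int = 1) -> np.ndarray:
    """Circular boolean mask covering the 10-90% rising limb of the main
    systolic pulse, dilated by ``dilate`` samples on each side."""
    n = q.size
    ip = int(np.argmax(q))
    shift = n // 2 - ip
    qr = np.roll(q, shift)
    pk = n // 2
    rng_ = qr[pk] - qr.min()
    if rng_ <= 0:
        raise NoSignalError("no upslope detectable")
    hi = qr.min() + 0.90 * rng_
    lo = qr.min() + 0.10 * rng_
    i = pk
    while i > 0 and qr[i - 1] >= hi:
        i -= 1
    j = i
    while j > 0 and lo <= qr[j - 1] <= qr[j]:
        j -= 1
    mask = np.zeros(n, bool)
    mask[max(j - dilate, 0):min(i + dilate, n - 1) + 1] = True
    return np.roll(mask, -shift)


def _fourier_resample(q: np.ndarray, dt: float, dt_new: float,
                      f_cut: float) -> tuple[np.ndarray, float]:
    """Trigonometric resampling of one periodic cycle onto a finer grid,
    discarding harmonics above ``f_cut`` (band-limited interpolation)."""
    n = q.size
    period = n * dt
    spec = np.fft.rfft(q)
    spec[np.fft.rfftfreq(n, dt) > f_cut] = 0.0
    m = max(int(round(period / dt_new)), n)
    out = np.zeros(m // 2 + 1, complex)
    k = min(spec.size, out.size)
    out[:k] = spec[:k]
    return np.fft.irfft(out, m) * (m / n), period / m


def _wrap_delay(d: float, period: float) -> float:
    return (d + period / 2.0) % period - period / 2.0


# ---------------------------------------------------------------------------
# wavelet estimator
# ---------------------------------------------------------------------------

def _cwt_periodic(x: np.ndarray, scales: np.ndarray, dt: float):
    """CWT with periodic boundary handling (three tiled cycles, center kept)."""
    x3 = np.concatenate([x, x, x])
    coef, freqs = pywt.cwt(x3, scales, _WAVELET, sampling_period=dt, method="fft")
    n = x.size
    return coef[:, n:2 * n], freqs


def _normalize(q: np.ndarray) -> np.ndarray:
    x = q - q.mean()
    m = np.abs(x).max()
    if m == 0:
        raise NoSignalError("flat (zero-variance) flow curve")
    return x / m


def _wavelet_scales(dt: float) -> np.ndarray:
    freqs = np.geomspace(_FMIN, _FMAX, _N_SCALES)
    return pywt.frequency2scale(_WAVELET, freqs * dt)


def _coarse_delay(qa: np.ndarray, qb: np.ndarray, dt: float) -> float:
    """Integer-sample circular cross-correlation delay, used to pick the
    phase branch at each wavelet scale."""
    n = qa.size
    a = qa - qa.mean()
    b = qb - qb.mean()
    r = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n)
    k = int(np.argmax(r))
    period = n * dt
    return (k * dt + period / 2.0) % period - period / 2.0


def _wavelet_delay_from_cwt(Wa, Wb, freqs, tmask, max_delay, init_delay=0.0):
    """Amplitude x f^2 weighted mean of per-scale cross-spectrum delays over
    the admissible region (reference upslope window, energetic scales).

    Each scale's phase delay is unwrapped to the 1/f branch nearest the
    coarse cross-correlation estimate ``init_delay`` before averaging, so
    delays beyond half a period of a scale do not alias.
    """
    Aa = np.abs(Wa[:, tmask])
    Ab = np.abs(Wb[:, tmask])
    if Aa.max() == 0 or Ab.max() == 0:
        raise LowQualityError("empty admissible time-frequency region")
    keep = (Aa >= 0.5 * Aa.max()) & (Ab >= 0.5 * Ab.max())
    cross = Wa[:, tmask] * np.conj(Wb[:, tmask])
    cs = np.where(keep, cross, 0.0).sum(axis=1)
    tau = np.angle(cs) / (2.0 * np.pi * freqs)
    tau = tau + np.round((init_delay - tau) * freqs) / freqs
    ok = (np.abs(cs) > 0) & (np.abs(tau) <= max_delay)
    if not ok.any():
        raise LowQualityError("empty admissible time-frequency region")
    w = (np.abs(cs) * freqs ** 2)[ok]
    delay = float(np.sum(w * tau[ok]) / np.sum(w))
    quality = float(np.sum(np.abs(cs)[ok]) / np.sum(np.abs(cross)))
    return delay, min(max(quality, 0.0), 1.0)


def wavelet_delay(qa, qb, time_axis, max_delay: float | None = None
                  ) -> tuple[float, float]:
    """Cross-wavelet phase delay of ``qb`` relative to ``qa`` (s).

    Returns ``(delay, quality)``; delay is positive when ``qb`` lags.
    ``max_delay`` bounds admissible per-scale delays (default: period/4,
    beyond which phases are treated as wrapped and discarded).
    """
    qa, qb, t, dt = _check_pair(qa, qb, time_axis)
    period = qa.size * dt
    if max_delay is None:
        max_delay = period / 4.0
    a = _normalize(qa)
    b = _normalize(qb)
    scales = _wavelet_scales(dt)
    Wa, freqs = _cwt_periodic(a, scales, dt)
    Wb, _ = _cwt_periodic(b, scales, dt)
    tmask = _upslope_mask(qa)
    init = _coarse_delay(a, b, dt)
    return _wavelet_delay_from_cwt(Wa, Wb, freqs, tmask, max_delay, init)


# ---------------------------------------------------------------------------
# foot-to-foot estimator
# ---------------------------------------------------------------------------

def _foot_time(q: np.ndarray, dt: float) -> tuple[float, float]:
    """Foot of the systolic upslope: intersection of the pre-upslope
    baseline with the tangent at maximal upslope.  Returns (time, quality
    ingredient = baseline noisiness relative to pulse height)."""
    qf, dtf = _fourier_resample(q, dt, _XCORR_FINE_DT, 12.0)
    n = qf.size
    period = n * dtf
    ip = int(np.argmax(qf))
    shift = n // 2 - ip
    qr = np.roll(qf, shift)
    pk = n // 2
    rng_ = qr[pk] - qr.min()
    if rng_ <= 0:
        raise NoSignalError("no upslope detectable")
    # pre-upslope region: from cycle start (diastole) to the 10% crossing
    lo_level = qr.min() + 0.10 * rng_
    j = pk
    while j > 0 and qr[j - 1] <= qr[j]:
        j -= 1
    pre = qr[:max(j, 1)]
    band = pre[pre <= np.quantile(pre, 0.10)] if pre.size else qr[:1]
    baseline = float(band.mean())
    base_sd = float(band.std())
    deriv = np.gradient(qr, dtf)
    seg = slice(max(j, 1), pk + 1)
    m = int(np.argmax(deriv[seg])) + seg.start
    slope = float(deriv[m])
    if slope <= 0:
        raise NoSignalError("no upslope detectable")
    t_foot = (m * dtf - (qr[m] - baseline) / slope - shift * dtf) % period
    quality = 1.0 - min(base_sd / rng_, 1.0)
    return t_foot, quality


def foot_delay(qa, qb, time_axis) -> tuple[float, float]:
    """Intersecting-tangent foot-to-foot delay of ``qb`` relative to ``qa``."""
    qa, qb, t, dt = _check_pair(qa, qb, time_axis)
    period = qa.size * dt
    fa, quala = _foot_time(qa, dt)
    fb, qualb = _foot_time(qb, dt)
    return _wrap_delay(fb - fa, period), min(quala, qualb)


# ---------------------------------------------------------------------------
# upslope cross-correlation estimator
# ---------------------------------------------------------------------------

def _xcorr_directed(qaf: np.ndarray, qbf: np.ndarray, dt: float,
                    dilate: int, max_delay: float) -> tuple[float, float]:
    """Delay of qbf relative to qaf using the upslope window of qaf."""
    n = qaf.size
    mask = _upslope_mask(qaf, dilate=dilate)
    idx = np.where(mask)[0]
    win = np.hanning(idx.size)
    x = (qaf[idx] - qaf[idx].mean()) * win
    xn = np.sqrt(np.sum(x * x))
    if xn == 0:
        raise NoSignalError("flat upslope window")
    K = int(round(max_delay / dt))
    lags = np.arange(-K, K + 1)
    scores = np.empty(lags.size)
    for j, k in enumerate(lags):
        y = qbf[(idx + k) % n]
        y = (y - y.mean()) * win
        den = xn * np.sqrt(np.sum(y * y))
        scores[j] = float(np.dot(x, y) / den) if den > 0 else 0.0
    kb = int(np.argmax(scores))
    peak = scores[kb]
    if peak < _XCORR_MIN_PEAK:
        raise LowQualityError(
            f"correlation peak {peak:.2f} below {_XCORR_MIN_PEAK}")
    # parabola over the contiguous near-peak region: at coarse acquisition
    # a 3-point fit would sit on noise wiggles of a broad peak
    lo = kb
    while lo > 0 and scores[lo - 1] >= 0.95 * peak:
        lo -= 1
    hi = kb
    while hi < scores.size - 1 and scores[hi + 1] >= 0.95 * peak:
        hi += 1
    if hi - lo < 2:
        lo, hi = max(kb - 1, 0), min(kb + 1, scores.size - 1)
    sel = slice(lo, hi + 1)
    c = np.polyfit(lags[sel], scores[sel], 2)
    if c[0] < 0:
        vertex = float(np.clip(-c[1] / (2.0 * c[0]), lags[lo], lags[hi]))
    else:
        vertex = float(lags[kb])
    return vertex * dt, float(min(max(peak, 0.0), 1.0))


def upslope_xcorr_delay(qa, qb, time_axis, max_delay: float | None = None
                        ) -> tuple[float, float]:
    """Normalized cross-correlation delay restricted to the systolic upslope.

    Both curves are resampled onto a 2 ms grid by band-limited trigonometric
    interpolation; the Hann-tapered upslope window of each curve is
    correlated against the other over all admissible lags, the peak refined
    to sub-sample precision by a parabola over the contiguous near-peak
    region, and the two directed estimates averaged — making the estimator
    antisymmetric by construction.  Raises :class:`LowQualityError` when
    the correlation peak is below 0.5.
    """
    qa, qb, t, dt0 = _check_pair(qa, qb, time_axis)
    period = qa.size * dt0
    if max_delay is None:
        max_delay = period / 4.0
    qaf, dt = _fourier_resample(qa, dt0, _XCORR_FINE_DT, _XCORR_F_CUT)
    qbf, _ = _fourier_resample(qb, dt0, _XCORR_FINE_DT, _XCORR_F_CUT)
    dilate = max(int(round(2 * dt0 / dt)), 1)
    d_ab, q_ab = _xcorr_directed(qaf, qbf, dt, dilate, max_delay)
    d_ba, q_ba = _xcorr_directed(qbf, qaf, dt, dilate, max_delay)
    return 0.5 * (d_ab - d_ba), min(q_ab, q_ba)


# ---------------------------------------------------------------------------
# multi-plane driver
# ---------------------------------------------------------------------------

_METHODS = {
    "wavelet": wavelet_delay,
    "foot": foot_delay,
    "xcorr": upslope_xcorr_delay,
}


def plane_delays(curves: FlowCurveSet, method: str = "wavelet",
                 reference: int | None = None,
                 max_delay: float | None = None) -> TransitTimeResult:
    """Delay of the reference plane's waveform relative to every plane.

    The reference defaults to the last (most distal) plane.  Planes whose
    estimate fails a quality gate are marked missing (NaN) rather than
    aborting; more than 50% missing raises
    :class:`InsufficientDataError`.
    """
    if method not in _METHODS:
        raise InvalidArgumentError(f"unknown method {method!r}")
    n = curves.n_planes
    if n < 2:
        raise InvalidArgumentError("need at least 2 planes")
    ref = n - 1 if reference is None else int(reference)
    if not 0 <= ref < n:
        raise InvalidArgumentError(f"reference index {ref} out of range")

    t = curves.time_axis
    dt = curves.dt
    period = curves.period
    if max_delay is None:
        max_delay = period / 4.0
    delays = np.full(n, np.nan)
    quality = np.full(n, np.nan)
    delays[ref] = 0.0
    quality[ref] = 1.0
    q_ref = curves.flow[ref]

    if method == "wavelet":
        # cache the CWT of every plane: each is used once, the reference 41x
        scales = _wavelet_scales(dt)
        W_ref, freqs = _cwt_periodic(_normalize(q_ref), scales, dt)
        for i in range(n):
            if i == ref:
                continue
            try:
                qi = _normalize(curves.flow[i])
                Wi, _ = _cwt_periodic(qi, scales, dt)
                tmask = _upslope_mask(curves.flow[i])
                init = _coarse_delay(qi, _normalize(q_ref), dt)
                d, q = _wavelet_delay_from_cwt(Wi, W_ref, freqs, tmask,
                                               max_delay, init)
            except (LowQualityError, NoSignalError):
                continue
            delays[i], quality[i] = d, q
    else:
        fn = _METHODS[method]
        for i in range(n):
            if i == ref:
                continue
            try:
                d, q = fn(curves.flow[i], q_ref, t)
            except (LowQualityError, NoSignalError):
                continue
            delays[i], quality[i] = d, q

    if np.isfinite(delays).sum() < 0.5 * n:
        raise InsufficientDataError(
            f"only {np.isfinite(delays).sum()} of {n} planes usable")
    return TransitTimeResult(reference_index=ref, delays=delays,
                             quality=quality, method=method)
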