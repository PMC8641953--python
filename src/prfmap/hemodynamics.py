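"""Hemodynamic response kernels and neural-to-BOLD convolution.

The BOLD signal is modeled as the neural drive convolved with a hemodynamic
response function (HRF).  Two kernels are provided, characterized by their
time-to-peak and peak-to-fall times:

* ``monkey``: time-to-peak 4.2 s, peak-to-fall 6.2 s (narrow)
* ``human``:  time-to-peak 4.8 s, peak-to-fall 12.6 s (canonical, wider)

The functional form is a double gamma (positive gamma minus a small, delayed
undershoot gamma).  Only the two timing statistics of the target kernels are
known, so the gamma parameters are solved numerically: the positive lobe's
scale is root-found so the kernel peaks exactly at the target time-to-peak,
and its shape is root-found so the first post-peak return to within 5% of
baseline occurs at peak + peak-to-fall.  "Fall" as the 5%-of-baseline
crossing is this package's operationalization and is configurable via
``fall_fraction``.

Neural predictions for fitting are sampled at half the repetition time
(TR/2, i.e. 1.25 s for TR = 2.5 s); convolution runs at that resolution and
the result is decimated to TR by averaging consecutive sample pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import gamma as gamma_dist

__all__ = ["HRFKernel", "make_hrf", "convolve_to_bold", "fwhm"]

#: (time_to_peak, peak_to_fall) in seconds for the packaged kernels
HRF_TIMINGS = {"monkey": (4.2, 6.2), "human": (4.8, 12.6)}


@dataclass(frozen=True)
class HRFKernel:
    """Sampled hemodynamic impulse response, normalized to unit peak."""

    samples: np.ndarray
    dt: float
    time_to_peak: float
    peak_to_fall: float
    label: str

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    def resample(self, dt: float) -> "HRFKernel":
        """Linear-interpolation resampling onto a new sample interval."""
        if dt == self.dt:
            return self
        t_new = np.arange(0.0, self.duration, dt)
        s = np.interp(t_new, self.times, self.samples)
        s = s / s.max()
        return HRFKernel(s, dt, self.time_to_peak, self.peak_to_fall, self.label)

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.samples]),
            header=f"time_s amplitude (label={self.label})",
        )


def _double_gamma(t: np.ndarray, shape1: float, scale1: float,
                  undershoot_ratio: float, undershoot_delay_scale: float) -> np.ndarray:
    """Positive gamma minus a delayed undershoot gamma, both unit-peak."""
    pos = gamma_dist.pdf(t, a=shape1, scale=scale1)
    peak1 = (shape1 - 1.0) * scale1
    pos = pos / gamma_dist.pdf(peak1, a=shape1, scale=scale1)
    # undershoot: same shape, stretched scale -> peaks later and wider
    scale2 = scale1 * undershoot_delay_scale
    neg = gamma_dist.pdf(t, a=shape1, scale=scale2)
    peak2 = (shape1 - 1.0) * scale2
    neg = neg / gamma_dist.pdf(peak2, a=shape1, scale=scale2)
    return pos - undershoot_ratio * neg


def _fall_time(t: np.ndarray, h: np.ndarray, fall_fraction: float) -> float:
    """Time after the peak at which |h| first drops within fall_fraction of
    the (unit) peak; inf if it never does."""
    ipk = int(np.argmax(h))
    rel = np.abs(h[ipk:]) / h[ipk]
    below = np.flatnonzero(rel <= fall_fraction)
    if below.size == 0:
        return np.inf
    i = below[0]
    # linear interpolation between the bracketing samples
    if i == 0:
        return 0.0
    y0, y1 = rel[i - 1], rel[i]
    frac = (y0 - fall_fraction) / (y0 - y1)
    return (i - 1 + frac) * (t[1] - t[0])


def make_hrf(
    label: str = "monkey",
    dt: float = 0.05,
    *,
    time_to_peak: float | None = None,
    peak_to_fall: float | None = None,
    duration: float = 32.0,
    undershoot_ratio: float = 0.10,
    undershoot_delay_scale: float = 1.8,
    fall_fraction: float = 0.05,
) -> HRFKernel:
    """Construct a unit-peak double-gamma HRF with prescribed timing.

    Parameters
    ----------
    label : "monkey" or "human"; selects the packaged timing pair unless
        ``time_to_peak``/``peak_to_fall`` are given explicitly.
    dt : sample interval in seconds; must be <= 0.25 s to resolve the peak.
    duration : kernel length in seconds (>= 30 s so the tail has decayed).
    undershoot_ratio : undershoot amplitude as a fraction of the peak.
    fall_fraction : the "fall" is the first post-peak return of |h| within
        this fraction of the peak.

    Raises
    ------
    ValueError for unknown labels or dt too coarse; RuntimeError if the
    parameter solve does not converge.
    """
    if dt > 0.25:
        raise ValueError(f"dt={dt} too coarse; need dt <= 0.25 s to resolve the peak")
    if time_to_peak is None or peak_to_fall is None:
        try:
            ttp, ptf = HRF_TIMINGS[label]
        except KeyError:
            raise ValueError(f"unknown HRF label {label!r}; expected 'monkey' or 'human'")
        time_to_peak = time_to_peak if time_to_peak is not None else ttp
        peak_to_fall = peak_to_fall if peak_to_fall is not None else ptf

    t_fine = np.arange(0.0, duration, 0.005)

    def solved_scale(shape1: float) -> float:
        # the undershoot pulls the argmax earlier than the positive lobe's
        # analytic peak, so root-find the scale for d/dt h(ttp) = 0
        def slope_at_peak(scale1: float) -> float:
            eps = 1e-3
            pts = np.array([time_to_peak - eps, time_to_peak + eps])
            h = _double_gamma(pts, shape1, scale1,
                              undershoot_ratio, undershoot_delay_scale)
            return h[1] - h[0]

        s0 = time_to_peak / (shape1 - 1.0)
        return optimize.brentq(slope_at_peak, s0, 2.0 * s0, xtol=1e-9)

    def solved_kernel(shape1: float) -> np.ndarray:
        scale1 = solved_scale(shape1)
        return _double_gamma(t_fine, shape1, scale1,
                             undershoot_ratio, undershoot_delay_scale)

    def fall_residual(shape1: float) -> float:
        h = solved_kernel(shape1)
        return _fall_time(t_fine, h, fall_fraction) - peak_to_fall

    # larger shape -> narrower kernel -> shorter fall time (monotone)
    lo, hi = 1.2, 60.0
    try:
        shape1 = optimize.brentq(fall_residual, lo, hi, xtol=1e-6)
    except ValueError as exc:
        raise RuntimeError(
            f"HRF parameter solve failed for ttp={time_to_peak}, fall={peak_to_fall}"
        ) from exc

    h_fine = solved_kernel(shape1)
    peak_err = abs(t_fine[np.argmax(h_fine)] - time_to_peak)
    if peak_err > 0.05:
        raise RuntimeError(f"HRF peak off target by {peak_err:.3f} s")

    t = np.arange(0.0, duration, dt)
    samples = np.interp(t, t_fine, h_fine)
    samples = samples / samples.max()
    return HRFKernel(samples, dt, time_to_peak, peak_to_fall, label)


def fwhm(kernel: HRFKernel) -> float:
    """Full width at half maximum of the positive lobe, seconds."""
    h = kernel.samples
    t = kernel.times
    above = h >= 0.5
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise ValueError("kernel never reaches half maximum")

    def cross(i0: int, i1: int) -> float:
        # interpolate the 0.5 crossing between samples i0 and i1
        y0, y1 = h[i0], h[i1]
        return t[i0] + (0.5 - y0) / (y1 - y0) * (t[i1] - t[i0])

    left = cross(idx[0] - 1, idx[0]) if idx[0] > 0 else t[0]
    right = cross(idx[-1], idx[-1] + 1) if idx[-1] + 1 < h.size else t[-1]
    return right - left


def convolve_to_bold(
    neural_prediction: np.ndarray, hrf: HRFKernel, tr: float
) -> np.ndarray:
    """Convolve a neural prediction sampled at TR/2 with the HRF and decimate
    to TR resolution.

    The prediction is treated as causal and zero before run start (runs begin
    with blank epochs, so zero-padding is consistent with rest).  Causal
    linear convolution is truncated to the input length, then consecutive
    sample pairs are averaged down to one value per TR.

    ``neural_prediction`` must have even length 2 * n_TR.
    """
    pred = np.asarray(neural_prediction, dtype=np.float64)
    if pred.ndim != 1:
        raise ValueError("neural_prediction must be 1-D")
    if pred.size % 2 != 0:
        raise ValueError("prediction length must be even (two samples per TR)")
    dt = tr / 2.0
    kernel = hrf.resample(dt)
    full = np.convolve(pred, kernel.samples)[: pred.size]
    return full.reshape(-1, 2).mean(axis=1)
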