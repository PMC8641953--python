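"""The four pRF spatial models and their predicted responses.

Each population receptive field (pRF) is an isotropic 2-D Gaussian profile
over visual space, and the predicted response to one binary stimulus frame
S is

    Resp_pred = g * [ sum_{x,y} S(x,y) * G(x,y) ] ** n

with unit-peak Gaussian G(x,y) = exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2)).

Model variants:

``P-LIN``   linear summation (n = 1), gain constrained positive.
``U-LIN``   linear summation, gain free to be negative (stimulus-driven
            suppression, i.e. negative pRFs).
``CSS``     compressive spatial summation: static power-law nonlinearity
            with exponent n (n < 1 -> subadditive), gain positive.
``DoG``     difference of Gaussians: excitatory center (sigma1) minus a
            broader suppressive surround (sigma2 > sigma1) scaled by
            amplitude a; summation linear (n = 1).

The pixel sum is divided by pixels_per_dva^2 (i.e. it approximates the
integral of S*G over visual space in dva^2), so predictions do not depend on
the rendering resolution.

Because the pRF size and the static nonlinearity interact, pRF size is
defined for every model as the standard deviation of the predicted response
profile to a point stimulus: sigma / sqrt(n).  For the DoG model the center
size sigma1 and surround size sigma2 are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

__all__ = ["MODELS", "PRFParams", "prf_field", "predict_response", "prf_size"]

MODELS = ("P-LIN", "U-LIN", "DoG", "CSS")


@dataclass(frozen=True)
class PRFParams:
    """Parameters of one pRF.

    x0, y0, sigma1, sigma2 are in dva; amp_surround (a) and exponent (n) are
    dimensionless; gain maps unit pRF-weighted stimulus drive (dva^2) to
    response units.
    """

    model: str
    x0: float
    y0: float
    sigma1: float
    gain: float = 1.0
    sigma2: float = np.nan
    amp_surround: float = 0.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not self.sigma1 > 0:
            raise ValueError("sigma1 must be positive")
        if self.model == "DoG":
            if not (self.sigma2 > self.sigma1):
                raise ValueError("DoG requires sigma2 > sigma1")
            if self.amp_surround < 0:
                raise ValueError("DoG surround amplitude must be >= 0")
        if self.model == "CSS":
            if not self.exponent > 0:
                raise ValueError("CSS exponent must be positive")
        elif self.exponent != 1.0:
            raise ValueError(f"{self.model} fixes the exponent at 1")
        if self.model in ("P-LIN", "CSS") and not self.gain > 0:
            raise ValueError(f"{self.model} requires positive gain")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))

    @property
    def polar_angle(self) -> float:
        """Polar angle in degrees, counterclockwise from the positive x axis."""
        return float(np.rad2deg(np.arctan2(self.y0, self.x0)))

    def with_gain(self, gain: float) -> "PRFParams":
        return replace(self, gain=gain)

    def to_record(self) -> dict:
        d = asdict(self)
        d["ecc"] = self.eccentricity
        d["polar_angle"] = self.polar_angle
        d["size"] = prf_size(self)[0]
        return d

    @classmethod
    def from_record(cls, rec: dict) -> "PRFParams":
        keys = ("model", "x0", "y0", "sigma1", "gain", "sigma2", "amp_surround", "exponent")
        return cls(**{k: rec[k] for k in keys if k in rec and rec[k] == rec[k]})


def prf_field(params: PRFParams, xgrid: np.ndarray, ygrid: np.ndarray) -> np.ndarray:
    """Per-pixel pRF weight map on the given coordinate grids (dva).

    Unit-peak Gaussian; DoG subtracts the surround Gaussian scaled by the
    surround amplitude, so the field can be negative away from the center.
    """
    d2 = (xgrid - params.x0) ** 2 + (ygrid - params.y0) ** 2
    g1 = np.exp(-d2 / (2.0 * params.sigma1**2))
    if params.model == "DoG":
        g2 = np.exp(-d2 / (2.0 * params.sigma2**2))
        return g1 - params.amp_surround * g2
    return g1


def predict_response(
    params: PRFParams,
    frames: np.ndarray,
    xgrid: np.ndarray,
    ygrid: np.ndarray,
    pixels_per_dva: float,
) -> np.ndarray:
    """Predicted response to each frame of a binary stimulus movie.

    frames : (T, H, W) or (T, H*W) array; xgrid/ygrid : (H, W) in dva.
    Returns a (T,) vector: gain * (integral of S*G in dva^2) ** n.  DoG
    drives can be negative (surround suppression below baseline); they pass
    through signed with n = 1.
    """
    field = prf_field(params, xgrid, ygrid).ravel()
    flat = frames.reshape(frames.shape[0], -1)
    if flat.shape[1] != field.size:
        raise ValueError(
            f"stimulus grid ({flat.shape[1]} px) does not match pRF grid ({field.size} px)"
        )
    drive = flat.astype(np.float64) @ field / float(pixels_per_dva) ** 2
    if params.exponent != 1.0:
        drive = np.power(np.clip(drive, 0.0, None), params.exponent)
    return params.gain * drive


def predict_from_stimulus(params: PRFParams, stim, bar_only: bool = False) -> np.ndarray:
    """Convenience wrapper taking an :class:`~prfmap.stimulus.EffectiveStimulus`."""
    frames = stim.bar_frames() if bar_only else stim.frames
    return predict_response(
        params, frames, stim.xgrid, stim.ygrid, stim.protocol.pixels_per_dva
    )


def prf_size(params: PRFParams) -> tuple[float, float]:
    """pRF size(s) in dva.

    Returns ``(size, surround_size)``.  For Gaussian models the size is the
    SD of the point-stimulus response profile: exp(-d^2/(2 sigma^2))^n is a
    Gaussian with SD sigma/sqrt(n).  For DoG the center size is sigma1 and
    the surround size sigma2; for the other models surround_size is NaN.
    """
    if params.model == "DoG":
        return params.sigma1, params.sigma2
    return params.sigma1 / np.sqrt(params.exponent), np.nan


def normalized_suppression(params: PRFParams) -> float:
    """Surround/center volume ratio a * (sigma2/sigma1)^2 of a DoG pRF.

    Values > 1 indicate net suppression (the surround's integrated weight
    exceeds the center's).
    """
    if params.model != "DoG":
        raise ValueError("normalized suppression is defined for DoG pRFs only")
    return params.amp_surround * (params.sigma2 / params.sigma1) ** 2
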