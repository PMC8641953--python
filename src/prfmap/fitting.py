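"""pRF model fitting: multi-start nonlinear least squares with split-half
cross-validated variance explained.

The central object is :class:`PRFRegressor`, a scikit-learn style estimator
that fits one pRF model to one unit's responses.  ``X`` is the stimulus
design (an :class:`~prfmap.stimulus.EffectiveStimulus`, or a prebuilt
:class:`PRFDesign` when fitting many units against the same stimulus) and
``y`` the unit's response vector: per-TR percent signal change for BOLD, or
per-bar-position response for electrophysiology.

Fitting is two-stage:

1. a coarse grid over center (x0, y0) and size sigma (and exponent for CSS),
   with the gain solved in closed form by least squares of the prediction
   shape onto the data; the top seeds by training R² are kept;
2. bounded local refinement of all parameters with
   ``scipy.optimize.least_squares`` from each seed, keeping the best
   training-loss solution.

Model accuracy is the cross-validated percentage of variance explained:
the data are split into two non-overlapping halves (odd and even runs or
repeats), each half is fitted independently, each fold's prediction is scored
against the *other* half, and the two R² values are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .hemodynamics import HRFKernel, convolve_to_bold
from .models import MODELS, PRFParams, prf_field, prf_size
from .stimulus import EffectiveStimulus

__all__ = [
    "PRFDesign",
    "PRFRegressor",
    "ResponseDataset",
    "FitResult",
    "grid_init",
    "fit_prf",
    "fit_population",
    "crossval_r2",
    "compare_models",
]


class PRFDesign:
    """Stimulus design shared by every unit recorded under one protocol.

    Precomputes the flattened frame matrix and, for BOLD, the machinery to
    upsample frame drives to TR/2 and convolve with the HRF.  Building one
    design and reusing it across units avoids recomputing the frame matrix.
    """

    def __init__(
        self,
        stim: EffectiveStimulus,
        hrf: HRFKernel | None = None,
        tr: float | None = None,
    ):
        self.stim = stim
        self.hrf = hrf
        self.tr = tr
        self.ppd = float(stim.protocol.pixels_per_dva)
        self.xflat = stim.xgrid.ravel()
        self.yflat = stim.ygrid.ravel()
        if hrf is not None:
            if tr is None:
                raise ValueError("tr is required when an HRF is supplied")
            step = stim.protocol.step_duration
            if np.isclose(step, tr):
                self._upsample = 2
            elif np.isclose(step, tr / 2.0):
                self._upsample = 1
            else:
                raise ValueError(
                    f"frame step {step} s must equal TR or TR/2 for BOLD designs"
                )
            self.frames_flat = stim.flat_frames(bar_only=False)
            self.n_out = (self.frames_flat.shape[0] * self._upsample) // 2
        else:
            # ephys: one response per bar position, blanks dropped
            self.frames_flat = stim.flat_frames(bar_only=True)
            self.n_out = self.frames_flat.shape[0]

    @property
    def is_bold(self) -> bool:
        return self.hrf is not None

    def drive(self, field_flat: np.ndarray) -> np.ndarray:
        """Frame-wise pRF drive in dva^2 for one (or many) field vectors."""
        return self.frames_flat @ field_flat / self.ppd**2

    def response_from_drive(self, drive: np.ndarray, exponent: float, gain: float) -> np.ndarray:
        """Apply static nonlinearity, gain, and (for BOLD) HRF convolution."""
        if exponent != 1.0:
            drive = np.power(np.clip(drive, 0.0, None), exponent)
        neural = gain * drive
        if not self.is_bold:
            return neural
        if self._upsample == 2:
            neural = np.repeat(neural, 2)
        return convolve_to_bold(neural, self.hrf, self.tr)

    def predict(self, params: PRFParams) -> np.ndarray:
        f = prf_field(params, self.xflat, self.yflat)
        return self.response_from_drive(self.drive(f), params.exponent, params.gain)


# ---------------------------------------------------------------------------
# cross-validated R^2


def crossval_r2(prediction: np.ndarray, held_out_data: np.ndarray) -> float:
    """Percentage of held-out variance explained, 100 * (1 - SS_res/SS_tot).

    SS_tot is taken about the held-out mean, so a prediction equal to that
    mean scores 0 and worse predictions score negative.
    """
    pred = np.asarray(prediction, dtype=np.float64)
    data = np.asarray(held_out_data, dtype=np.float64)
    if pred.shape != data.shape:
        raise ValueError("prediction and data lengths differ")
    ss_tot = np.sum((data - data.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("held-out data has zero variance")
    ss_res = np.sum((data - pred) ** 2)
    return 100.0 * (1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# parameter vector packing (internal)
#
# P-LIN/U-LIN: (x0, y0, log sigma, gain)
# CSS:         (x0, y0, log sigma, exponent, gain)
# DoG:         (x0, y0, log sigma1, log k, amp_surround, gain), sigma2 = k*sigma1

_BIG_GAIN = 1e6
_MIN_GAIN = 1e-9


def _pack(params: PRFParams) -> np.ndarray:
    if params.model == "CSS":
        return np.array([params.x0, params.y0, np.log(params.sigma1),
                         params.exponent, params.gain])
    if params.model == "DoG":
        return np.array([params.x0, params.y0, np.log(params.sigma1),
                         np.log(params.sigma2 / params.sigma1),
                         params.amp_surround, params.gain])
    return np.array([params.x0, params.y0, np.log(params.sigma1), params.gain])


def _unpack(model: str, vec: np.ndarray) -> PRFParams:
    x0, y0, logs = vec[0], vec[1], vec[2]
    sigma1 = float(np.exp(logs))
    if model == "CSS":
        return PRFParams(model, x0, y0, sigma1, gain=vec[4], exponent=vec[3])
    if model == "DoG":
        k = float(np.exp(vec[3]))
        return PRFParams(model, x0, y0, sigma1, gain=vec[5],
                         sigma2=k * sigma1, amp_surround=vec[4])
    return PRFParams(model, x0, y0, sigma1, gain=vec[3])


def _bounds(model: str, aperture: float, allow_negative_gain: bool) -> tuple[np.ndarray, np.ndarray]:
    r15 = 1.5 * aperture / 2.0
    lo_sig, hi_sig = np.log(0.05), np.log(2.0 * aperture)
    glo = -_BIG_GAIN if allow_negative_gain else _MIN_GAIN
    if model == "CSS":
        lo = [-r15, -r15, lo_sig, 0.05, glo]
        hi = [r15, r15, hi_sig, 1.5, _BIG_GAIN]
    elif model == "DoG":
        lo = [-r15, -r15, lo_sig, np.log(1.05), 0.0, glo]
        hi = [r15, r15, hi_sig, np.log(20.0), 3.0, _BIG_GAIN]
    else:
        lo = [-r15, -r15, lo_sig, glo]
        hi = [r15, r15, hi_sig, _BIG_GAIN]
    return np.asarray(lo), np.asarray(hi)


# ---------------------------------------------------------------------------
# grid initialization


def grid_init(
    design: PRFDesign,
    data: np.ndarray,
    model: str,
    *,
    n_xy: int = 9,
    n_sigma: int = 6,
    exponents: Sequence[float] = (0.25, 0.5, 1.0),
    top_k: int = 3,
) -> list[PRFParams]:
    """Coarse-grid seeds for the nonlinear refinement.

    Candidate centers cover a square out to 1.5x the aperture radius (pRF
    centers may lie outside the stimulated field), sizes are log-spaced from
    0.1 dva to the aperture diameter, and for CSS the exponent takes a few
    discrete values.  For each candidate shape, the gain is the closed-form
    least-squares projection of the prediction onto the data; the ``top_k``
    candidates by training R² are returned as seeds.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    data = np.asarray(data, dtype=np.float64)
    if data.size != design.n_out:
        raise ValueError(f"data length {data.size} != design length {design.n_out}")
    if np.ptp(data) == 0:
        raise ValueError("degenerate (constant) data half: unit is unfittable")

    ap = design.stim.protocol.aperture_diameter
    r15 = 1.5 * ap / 2.0
    centers = np.linspace(-r15, r15, n_xy)
    sigmas = np.geomspace(0.1, ap, n_sigma)
    exps = tuple(exponents) if model == "CSS" else (1.0,)
    allow_neg = model == "U-LIN"
    # DoG candidate shapes: surround at k * sigma with amplitude a
    dog_shapes = ((2.0, 0.25), (2.0, 0.75)) if model == "DoG" else ((np.nan, 0.0),)

    # drive vectors for all (x0, y0, sigma) combos in one matmul
    xs, ys, ss = np.meshgrid(centers, centers, sigmas, indexing="ij")
    xs, ys, ss = xs.ravel(), ys.ravel(), ss.ravel()
    d2 = (
        (design.xflat[:, None] - xs[None, :]) ** 2
        + (design.yflat[:, None] - ys[None, :]) ** 2
    )
    center_drives = design.drive(np.exp(-d2 / (2.0 * ss[None, :] ** 2)))
    if model == "DoG":
        k = dog_shapes[0][0]
        surround_drives = design.drive(np.exp(-d2 / (2.0 * (k * ss[None, :]) ** 2)))

    y = data
    ss_tot = np.sum((y - y.mean()) ** 2)
    # drop numerically degenerate candidates (pRF so far out that the drive
    # vanishes and the closed-form gain blows up)
    norms = np.linalg.norm(center_drives, axis=0)
    valid = norms > 1e-9 * norms.max()

    scored: list[tuple[float, PRFParams]] = []
    for k, a in dog_shapes:
        for n_exp in exps:
            for j in np.flatnonzero(valid):
                drive = center_drives[:, j]
                if model == "DoG":
                    drive = drive - a * surround_drives[:, j]
                shape = design.response_from_drive(drive, n_exp, 1.0)
                denom = float(shape @ shape)
                if denom <= 0:
                    continue
                gain = float(shape @ y) / denom
                if not allow_neg and gain <= 0:
                    gain = _MIN_GAIN
                resid = y - gain * shape
                r2 = 100.0 * (1.0 - np.sum(resid**2) / ss_tot)
                if model == "DoG":
                    p = PRFParams(model, xs[j], ys[j], ss[j], gain=max(gain, _MIN_GAIN),
                                  sigma2=k * ss[j], amp_surround=a)
                elif model == "CSS":
                    p = PRFParams(model, xs[j], ys[j], ss[j],
                                  gain=max(gain, _MIN_GAIN), exponent=n_exp)
                else:
                    p = PRFParams(model, xs[j], ys[j], ss[j],
                                  gain=gain if allow_neg else max(gain, _MIN_GAIN))
                scored.append((r2, p))
    scored.sort(key=lambda t: -t[0])
    return [p for _, p in scored[:top_k]]


# ---------------------------------------------------------------------------
# the estimator


class PRFRegressor(RegressorMixin, BaseEstimator):
    """Fit one pRF model to one unit's responses.

    Parameters
    ----------
    model : {"P-LIN", "U-LIN", "CSS", "DoG"}
        pRF model variant (see :mod:`prfmap.models`).
    hrf, tr : HRF kernel and repetition time in seconds, for BOLD data;
        leave both None for electrophysiology position responses.
    n_xy, n_sigma, top_k : coarse-grid density and number of seeds refined.
    max_nfev : cap on objective evaluations per local refinement.

    Attributes (after ``fit``)
    --------------------------
    params_ : the best-fit :class:`PRFParams`
    x0_, y0_, sigma1_, sigma2_, amp_surround_, exponent_, gain_ : floats
    size_ : pRF size in dva (SD of the point-stimulus response profile)
    r2_train_ : training percentage of variance explained
    n_evals_ : total objective evaluations
    converged_ : True if any local refinement reported convergence
    """

    def __init__(
        self,
        model: str = "CSS",
        hrf: HRFKernel | None = None,
        tr: float | None = None,
        n_xy: int = 9,
        n_sigma: int = 6,
        top_k: int = 3,
        max_nfev: int = 200,
    ):
        self.model = model
        self.hrf = hrf
        self.tr = tr
        self.n_xy = n_xy
        self.n_sigma = n_sigma
        self.top_k = top_k
        self.max_nfev = max_nfev

    # -- design handling ----------------------------------------------------

    def _as_design(self, X) -> PRFDesign:
        if isinstance(X, PRFDesign):
            return X
        if isinstance(X, EffectiveStimulus):
            return PRFDesign(X, hrf=self.hrf, tr=self.tr)
        raise TypeError(
            "X must be an EffectiveStimulus or PRFDesign describing the bar sweep"
        )

    # -- scikit-learn API ---------------------------------------------------

    def fit(self, X, y) -> "PRFRegressor":
        design = self._as_design(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        seeds = grid_init(
            design, y, self.model,
            n_xy=self.n_xy, n_sigma=self.n_sigma, top_k=self.top_k,
        )
        allow_neg = self.model == "U-LIN"
        lo, hi = _bounds(self.model, design.stim.protocol.aperture_diameter, allow_neg)

        def residuals(vec: np.ndarray) -> np.ndarray:
            p = _unpack_unchecked(self.model, vec)
            f = _field_unchecked(p, design.xflat, design.yflat)
            return design.response_from_drive(design.drive(f), p["exponent"], p["gain"]) - y

        best = None
        n_evals = 0
        converged = False
        for seed in seeds:
            x0 = np.clip(_pack(seed), lo, hi)
            try:
                res = optimize.least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf",
                    max_nfev=self.max_nfev, xtol=1e-10, ftol=1e-10, gtol=1e-10,
                )
            except Exception:
                continue
            n_evals += res.nfev
            converged = converged or res.status > 0
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all refinement starts failed")

        params = _unpack(self.model, best.x)
        self.params_ = params
        self.x0_ = params.x0
        self.y0_ = params.y0
        self.sigma1_ = params.sigma1
        self.sigma2_ = params.sigma2
        self.amp_surround_ = params.amp_surround
        self.exponent_ = params.exponent
        self.gain_ = params.gain
        self.size_ = prf_size(params)[0]
        self.r2_train_ = crossval_r2(design.predict(params), y)
        self.n_evals_ = n_evals
        self.converged_ = converged
        return self

    def predict(self, X) -> np.ndarray:
        design = self._as_design(X)
        return design.predict(self.params_)

    def score(self, X, y) -> float:
        """Coefficient of determination as a fraction (sklearn convention)."""
        return crossval_r2(self.predict(X), np.asarray(y, dtype=np.float64).ravel()) / 100.0


def _unpack_unchecked(model: str, vec: np.ndarray) -> dict:
    # hot path: the optimizer may propose vectors violating dataclass
    # invariants transiently; evaluate without validation
    d = {"x0": vec[0], "y0": vec[1], "sigma1": np.exp(vec[2]),
         "exponent": 1.0, "amp_surround": 0.0, "sigma2": np.inf}
    if model == "CSS":
        d["exponent"] = vec[3]
        d["gain"] = vec[4]
    elif model == "DoG":
        d["sigma2"] = np.exp(vec[2] + vec[3])
        d["amp_surround"] = vec[4]
        d["gain"] = vec[5]
    else:
        d["gain"] = vec[3]
    return d


def _field_unchecked(p: dict, xflat: np.ndarray, yflat: np.ndarray) -> np.ndarray:
    d2 = (xflat - p["x0"]) ** 2 + (yflat - p["y0"]) ** 2
    f = np.exp(-d2 / (2.0 * p["sigma1"] ** 2))
    if p["amp_surround"] != 0.0:
        f = f - p["amp_surround"] * np.exp(-d2 / (2.0 * p["sigma2"] ** 2))
    return f


# ---------------------------------------------------------------------------
# datasets and the split-half fitting driver


@dataclass
class ResponseDataset:
    """Responses of many units to one stimulus, split into odd/even halves.

    ``data_odd`` and ``data_even`` are (n_units, T) arrays holding the
    average of the odd-numbered and even-numbered runs (or repeats).  For
    modality "bold" T is the number of TRs and ``hrf``/``tr`` must be set;
    for "mua"/"lfp_band" T is the number of bar positions.
    """

    data_odd: np.ndarray
    data_even: np.ndarray
    modality: str
    stim: EffectiveStimulus
    hrf: HRFKernel | None = None
    tr: float | None = None
    unit_ids: np.ndarray | None = None
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data_odd = np.atleast_2d(np.asarray(self.data_odd, dtype=np.float64))
        self.data_even = np.atleast_2d(np.asarray(self.data_even, dtype=np.float64))
        if self.data_odd.shape != self.data_even.shape:
            raise ValueError("odd and even halves must have identical shape")
        if self.modality not in ("bold", "mua", "lfp_band"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "bold" and (self.hrf is None or self.tr is None):
            raise ValueError("BOLD datasets require hrf and tr")
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.n_units)
        self._design: PRFDesign | None = None

    @property
    def n_units(self) -> int:
        return self.data_odd.shape[0]

    @property
    def design(self) -> PRFDesign:
        if self._design is None:
            self._design = PRFDesign(self.stim, hrf=self.hrf, tr=self.tr)
        return self._design


@dataclass
class FitResult:
    """One unit's fit: parameters plus split-half cross-validated R²."""

    params: PRFParams
    r2_cv: float
    r2_fold: tuple[float, float]
    r2_train: float
    n_evals: int
    converged: bool

    def to_record(self) -> dict:
        rec = self.params.to_record()
        rec.update(
            r2_cv=self.r2_cv,
            r2_fold_odd=self.r2_fold[0],
            r2_fold_even=self.r2_fold[1],
            r2_train=self.r2_train,
            converged=self.converged,
        )
        return rec


def fit_prf(
    model: str,
    dataset: ResponseDataset,
    unit: int,
    refit_full: bool = True,
    **estimator_kw,
) -> FitResult:
    """Split-half fit of one unit.

    Each half is fitted independently; each fold's parameters are scored on
    the *other* half and the two R² values averaged.  With ``refit_full``
    (the default) the reported parameters come from a refit on the mean of
    both halves — all the data — while the cross-validated R² still comes
    from the fold fits; otherwise the better fold's parameters are reported.
    """
    design = dataset.design
    y_odd = dataset.data_odd[unit]
    y_even = dataset.data_even[unit]
    kw = dict(model=model, hrf=dataset.hrf, tr=dataset.tr, **estimator_kw)
    est_odd = PRFRegressor(**kw).fit(design, y_odd)
    est_even = PRFRegressor(**kw).fit(design, y_even)
    r2_odd_on_even = crossval_r2(design.predict(est_odd.params_), y_even)
    r2_even_on_odd = crossval_r2(design.predict(est_even.params_), y_odd)
    n_evals = est_odd.n_evals_ + est_even.n_evals_
    converged = est_odd.converged_ and est_even.converged_
    if refit_full:
        best = PRFRegressor(**kw).fit(design, (y_odd + y_even) / 2.0)
        n_evals += best.n_evals_
        converged = converged and best.converged_
    else:
        best = est_odd if est_odd.r2_train_ >= est_even.r2_train_ else est_even
    # training R² is reported on the fitted halves (the fold fits), matching
    # how inclusion thresholds are applied
    r2_train = max(est_odd.r2_train_, est_even.r2_train_)
    folds = (r2_odd_on_even, r2_even_on_odd)
    return FitResult(
        params=best.params_,
        r2_cv=float(np.mean(folds)),
        r2_fold=folds,
        r2_train=r2_train,
        n_evals=n_evals,
        converged=converged,
    )


def fit_population(
    model: str,
    dataset: ResponseDataset,
    units: Sequence[int] | None = None,
    signal_type: str | None = None,
    **estimator_kw,
) -> pd.DataFrame:
    """Fit every unit of a dataset; returns one row per unit.

    Units whose grid stage rejects the data (constant halves) get NaN rows.
    """
    if units is None:
        units = range(dataset.n_units)
    rows = []
    for u in units:
        try:
            fr = fit_prf(model, dataset, u, **estimator_kw)
            rec = fr.to_record()
        except (ValueError, RuntimeError):
            rec = {"model": model, "r2_cv": np.nan}
        rec["unit"] = dataset.unit_ids[u]
        rec["signal_type"] = signal_type or dataset.modality
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model comparison


def compare_models(
    fit_tables: dict[str, pd.DataFrame],
    threshold_r2: float = 5.0,
) -> dict:
    """Rank pRF models by cross-validated R² across a unit population.

    Units are included when their best model exceeds ``threshold_r2``
    percent cross-validated R².  Returns the Kruskal–Wallis omnibus test
    across models, Tukey-HSD multiple comparisons of mean rank, and pairwise
    Wilcoxon signed-rank tests (the same units underlie every column).
    """
    if len(fit_tables) < 2:
        raise ValueError("need at least two models to compare")
    models = list(fit_tables)
    r2 = pd.DataFrame({m: t.set_index("unit")["r2_cv"] for m, t in fit_tables.items()})
    r2 = r2.dropna()
    keep = r2.max(axis=1) > threshold_r2
    r2 = r2[keep]
    if r2.empty:
        raise ValueError(f"no units exceed the R² threshold of {threshold_r2}%")

    h_stat, p_kw = stats.kruskal(*[r2[m].to_numpy() for m in models])

    # Tukey HSD multiple comparisons of mean rank: rank the pooled R² values,
    # then run Tukey's procedure on the ranks
    pooled = np.concatenate([r2[m].to_numpy() for m in models])
    labels = np.concatenate([[m] * len(r2) for m in models])
    ranks = stats.rankdata(pooled)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tukey = pairwise_tukeyhsd(ranks, labels)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )

    pairwise = []
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            da, db = r2[a].to_numpy(), r2[b].to_numpy()
            if np.allclose(da, db):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(da, db)
            pairwise.append(
                {"model_a": a, "model_b": b, "wilcoxon_stat": float(stat),
                 "p_value": float(p), "median_diff": float(np.median(da - db))}
            )

    ranking = r2.rank(axis=1).mean().sort_values(ascending=False)
    return {
        "n_units": int(len(r2)),
        "kruskal_h": float(h_stat),
        "kruskal_df": len(models) - 1,
        "kruskal_p": float(p_kw),
        "mean_rank": ranking.to_dict(),
        "best_model": ranking.index[0],
        "tukey": tukey_df,
        "pairwise_wilcoxon": pd.DataFrame(pairwise),
        "median_r2": r2.median().to_dict(),
    }
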