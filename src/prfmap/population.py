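"""Population-level comparisons of pRF estimates across signal types.

Covers four analyses used to relate BOLD-, MUA- and LFP-band-derived pRFs:

* **Separation index**: SI = distance between two RF centers divided by the
  sum of their sizes; SI < 1 means the RFs overlap.
* **Negative-pRF classification**: units are labelled positive or negative
  by the sign of the fitted U-LIN gain (negative gain = stimulus-driven
  suppression).
* **Eccentricity-size relation**: per-signal linear regression of pRF size
  on eccentricity, with 2-dva binned means +/- SEM for display.
* **Slope comparison across signals**: a linear model
  ``size ~ eccentricity * signal_type``; the interaction F-test asks whether
  the eccentricity-size slope differs between signal types, with pairwise
  reference-vs-signal contrasts.

The slope comparison uses a fixed-effects linear model with the
signal x eccentricity interaction rather than a mixed model; a hook
(``model_backend``) allows swapping in a mixed-model fitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .models import PRFParams, prf_size

__all__ = [
    "SlopeFit",
    "separation_index",
    "classify_negative",
    "ecc_size_relation",
    "compare_slopes",
]

SIGNAL_TYPES = ("bold", "mua", "theta", "alpha", "beta", "gamma_low", "gamma_high")


def _center_and_size(prf) -> tuple[float, float, float]:
    if isinstance(prf, PRFParams):
        return prf.x0, prf.y0, prf_size(prf)[0]
    x, y, size = prf
    return float(x), float(y), float(size)


def separation_index(prf_a, prf_b) -> float:
    """SI = Euclidean center distance / (size_a + size_b).

    Arguments are :class:`PRFParams` or ``(x, y, size)`` triples.  SI < 1
    indicates overlapping RFs.  Symmetric and invariant to a common rescaling
    of all positions and sizes.
    """
    xa, ya, sa = _center_and_size(prf_a)
    xb, yb, sb = _center_and_size(prf_b)
    if sa <= 0 or sb <= 0:
        raise ValueError("separation index requires positive sizes")
    return float(np.hypot(xa - xb, ya - yb) / (sa + sb))


def classify_negative(fit_table: pd.DataFrame) -> pd.Series:
    """Positive/negative pRF labels from the sign of the U-LIN gain.

    ``fit_table`` must hold U-LIN fits with a ``gain`` column; zero gain is
    labelled "indeterminate".
    """
    if "gain" not in fit_table.columns:
        raise ValueError("fit table lacks a gain column")
    if "model" in fit_table.columns:
        tab = fit_table[fit_table["model"] == "U-LIN"]
        if tab.empty:
            raise ValueError("no U-LIN fits present")
    else:
        tab = fit_table
    labels = np.where(tab["gain"] > 0, "positive",
                      np.where(tab["gain"] < 0, "negative", "indeterminate"))
    return pd.Series(labels, index=tab.index, name="prf_sign")


@dataclass(frozen=True)
class SlopeFit:
    """Linear eccentricity-size relation for one signal type."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    p_slope: float
    n_units: int
    r_squared: float


def ecc_size_relation(
    table: pd.DataFrame,
    bin_width: float = 2.0,
    r2_threshold: float | None = None,
) -> tuple[SlopeFit, pd.DataFrame]:
    """Linear regression of pRF size on eccentricity, plus binned means.

    The slope, its 95% CI and p-value come from the unbinned per-unit
    regression; the returned frame holds half-open ``bin_width``-dva
    eccentricity-bin means and SEMs for display.  Rows with ``r2_cv`` at or
    below ``r2_threshold`` (percent) are excluded first.
    """
    tab = table.dropna(subset=["ecc", "size"])
    if r2_threshold is not None and "r2_cv" in tab.columns:
        tab = tab[tab["r2_cv"] > r2_threshold]
    if len(tab) < 3:
        raise ValueError(f"need >= 3 units, got {len(tab)}")

    X = sm.add_constant(tab["ecc"].to_numpy())
    fit = sm.OLS(tab["size"].to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)
    slope_fit = SlopeFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        p_slope=float(fit.pvalues[1]),
        n_units=int(len(tab)),
        r_squared=float(fit.rsquared),
    )

    bins = np.floor(tab["ecc"].to_numpy() / bin_width).astype(int)
    grouped = tab.assign(ecc_bin=bins).groupby("ecc_bin")["size"]
    binned = pd.DataFrame(
        {
            "ecc_bin_left": grouped.mean().index * bin_width,
            "mean_size": grouped.mean().to_numpy(),
            "sem_size": grouped.sem().to_numpy(),
            "n": grouped.count().to_numpy(),
        }
    ).reset_index(drop=True)
    return slope_fit, binned


def compare_slopes(
    tables: dict[str, pd.DataFrame] | pd.DataFrame,
    reference: str | None = None,
    r2_threshold: float | None = None,
    model_backend=None,
) -> dict:
    """Test whether the eccentricity-size slope differs between signal types.

    Fits ``size ~ ecc * C(signal_type)`` across all units and reports the
    interaction F-test, per-signal slopes, and pairwise reference-vs-signal
    interaction contrasts (each pair refitted on its own subset).  With
    identical data under two labels the contrast F is exactly 0.

    ``model_backend`` may be a callable ``(formula, data) -> fitted model``
    to swap in e.g. a mixed-effects fitter; default is OLS.
    """
    if isinstance(tables, dict):
        frames = []
        for sig, t in tables.items():
            f = t.copy()
            f["signal_type"] = sig
            frames.append(f)
        data = pd.concat(frames, ignore_index=True)
    else:
        data = tables.copy()
    if "signal_type" not in data.columns:
        raise ValueError("need a signal_type column or a dict of tables")
    data = data.dropna(subset=["ecc", "size"])
    if r2_threshold is not None and "r2_cv" in data.columns:
        data = data[data["r2_cv"] > r2_threshold]
    signals = sorted(data["signal_type"].unique())
    if len(signals) < 2:
        raise ValueError("need >= 2 signal types")

    fitter = model_backend or (lambda formula, d: smf.ols(formula, data=d).fit())
    full = fitter("size ~ ecc * C(signal_type)", data)
    anova = sm.stats.anova_lm(full, typ=2)
    inter_row = anova.loc["ecc:C(signal_type)"]
    interaction = {
        "F": float(inter_row["F"]),
        "df": int(inter_row["df"]),
        "df_resid": int(anova.loc["Residual", "df"]),
        "p": float(inter_row["PR(>F)"]),
    }

    slopes = {}
    for sig in signals:
        sub = data[data["signal_type"] == sig]
        try:
            slopes[sig], _ = ecc_size_relation(sub)
        except ValueError:
            slopes[sig] = None

    reference = reference or signals[0]
    contrasts = []
    for sig in signals:
        if sig == reference:
            continue
        sub = data[data["signal_type"].isin([reference, sig])]
        pair_fit = fitter("size ~ ecc * C(signal_type)", sub)
        pair_anova = sm.stats.anova_lm(pair_fit, typ=2)
        row = pair_anova.loc["ecc:C(signal_type)"]
        f_val = float(row["F"])
        # identical data under two labels gives an interaction coefficient of
        # exactly zero; snap float roundoff to 0
        if np.isnan(f_val) or f_val < 1e-10:
            f_val = 0.0
        contrasts.append(
            {"reference": reference, "signal": sig, "F": f_val,
             "p": float(row["PR(>F)"])}
        )
    return {
        "interaction": interaction,
        "slopes": slopes,
        "contrasts": pd.DataFrame(contrasts),
        "n_units": int(len(data)),
        "signals": signals,
    }
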