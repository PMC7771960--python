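"""Shared-CV Gaussian noise model and categorical response classification.

Each replicate measurement of a feature (a gene's TPM or a peak's
normalized fragment counts) is modeled as a draw from
``Normal(mean, (mean * CV)^2)`` where a single coefficient of variation is
shared by all doses of a signal.  The per-dose CV uses the small-sample
unbiased estimator ``(1 + 1/(4n)) * s / mean`` and the shared CV is the
arithmetic mean over doses, so the variance of a condition is informed by
all nine samples of that signal rather than its three replicates alone.

The combined response of a feature at a dose is classified by asking where
the perfectly additive prediction ``x0 + dA + dB`` and the perfectly
multiplicative prediction ``x0 * (xA/x0) * (xB/x0)`` fall relative to the
80% confidence interval of the combined treatment's estimated Gaussian
(the interval of single observations, ``xAB +/- z * xAB * CV``).
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import REFERENCE_SIGNAL, TREATMENT_DOSES

GENE_CATEGORIES = ("sub_additive", "additive", "between_add_mult",
                   "multiplicative", "super_multiplicative", "ambiguous")
PEAK_CATEGORIES = ("sub_additive", "additive", "super_additive")

RESPONSE_COLUMNS = ["feature_id", "dose", "x0", "dA", "dB", "xAB",
                    "cv_both", "ci_lo", "ci_hi", "pred_add", "pred_mult", "valid"]


# ---------------------------------------------------------------------------
# CV estimation

def estimate_cv(replicates_per_dose: Iterable[Sequence[float]]) -> float:
    """Pooled coefficient of variation for one (feature, signal).

    Parameters
    ----------
    replicates_per_dose
        One sequence of replicate values per dose (each needs n >= 2 and a
        positive mean).

    Returns
    -------
    The arithmetic mean over doses of ``(1 + 1/(4n)) * s / mean`` with
    ``s`` the (n-1)-denominator sample standard deviation.  Doses with a
    non-positive mean are excluded; if no dose is usable, NaN.
    """
    per_dose = []
    for values in replicates_per_dose:
        arr = np.asarray(values, dtype=float)
        n = arr.size
        if n < 2:
            raise ValueError("CV estimation needs at least 2 replicates per dose")
        mean = arr.mean()
        if mean <= 0:
            continue
        s = arr.std(ddof=1)
        per_dose.append((1.0 + 1.0 / (4.0 * n)) * s / mean)
    if not per_dose:
        return float("nan")
    return float(np.mean(per_dose))


def fit_noise_model(values: pd.DataFrame, annotations: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate per-(feature, signal, dose) means and the shared CV.

    Parameters
    ----------
    values
        Long table with columns ``feature_id, sample_id, value``.
    annotations
        Sample table with columns ``sample_id, signal, dose, replicate``.

    Returns
    -------
    (means, cvs)
        ``means``: feature_id, signal, dose, mean, sd, n
        ``cvs``: feature_id, signal, cv  (NaN when no dose had a positive
        mean; such features are excluded from classification downstream).
    """
    merged = values.merge(annotations[["sample_id", "signal", "dose"]],
                          on="sample_id", validate="many_to_one")
    grouped = merged.groupby(["feature_id", "signal", "dose"], observed=True)["value"]
    means = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()

    # per-dose unbiased CV, then average over the usable doses of a signal
    with np.errstate(divide="ignore", invalid="ignore"):
        per_dose_cv = (1.0 + 1.0 / (4.0 * means["n"])) * means["sd"] / means["mean"]
    per_dose_cv = per_dose_cv.where(means["mean"] > 0)
    cv_frame = means[["feature_id", "signal"]].copy()
    cv_frame["cv_dose"] = per_dose_cv
    cvs = (cv_frame.groupby(["feature_id", "signal"], observed=True)["cv_dose"]
           .mean().rename("cv").reset_index())
    return means, cvs


# ---------------------------------------------------------------------------
# Response estimates

def interval_quantile(level: float, df=None):
    """Two-sided central-interval multiplier: z, or t when ``df`` is given.

    The t quantile accounts for the sampling noise of the estimated CV
    (the interval half-width is a multiple of the *estimated* sd); with
    the shared-CV model the natural df is m*(n-1) over the m doses.
    """
    p = 0.5 + level / 2.0
    if df is None:
        return stats.norm.ppf(p)
    return stats.t.ppf(p, df)


def normal_interval(mean: np.ndarray, sd: np.ndarray, level: float, df=None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Central ``level`` interval of Normal(mean, sd^2) (t-based if df given)."""
    q = interval_quantile(level, df)
    return mean - q * sd, mean + q * sd


def build_response_estimate(x0: float, xA: float, xB: float, xAB: float,
                            cv_both: float, ci_level: float = 0.80,
                            df=None) -> dict:
    """Single-feature response estimate (scalar convenience wrapper).

    With ``df=None`` the interval uses the normal quantile; pass the CV
    estimator's degrees of freedom for the calibrated t interval the
    table-level builder uses by default.
    """
    dA = xA - x0
    dB = xB - x0
    sd = xAB * cv_both
    lo, hi = normal_interval(np.asarray(xAB), np.asarray(sd), ci_level, df)
    valid = x0 > 0 and np.isfinite(cv_both)
    return {
        "x0": x0, "dA": dA, "dB": dB, "xAB": xAB, "cv_both": cv_both,
        "ci_lo": float(lo), "ci_hi": float(hi),
        "pred_add": x0 + dA + dB,
        "pred_mult": x0 * (xA / x0) * (xB / x0) if x0 > 0 else float("nan"),
        "valid": bool(valid),
    }


def build_response_table(means: pd.DataFrame, cvs: pd.DataFrame,
                         ci_level: float = 0.80,
                         doses: Sequence[str] = TREATMENT_DOSES,
                         reference_signal: str = REFERENCE_SIGNAL,
                         ci_df: float | str | None = "auto") -> pd.DataFrame:
    """Per-(feature, dose) response estimates with predictions and CI.

    The baseline x0 is the reference-control mean (dose ``none``); dA and
    dB are the matched-dose individual effects; the interval describes the
    combined-treatment Gaussian.  ``ci_df="auto"`` (default) uses a t
    quantile with the combined signal's CV degrees of freedom, summed
    (n-1) over its doses, which keeps the interval's realized coverage at
    its nominal level despite the estimated CV; ``ci_df=None`` uses the
    plain normal quantile.  Features with x0 <= 0 or a missing condition
    mean are kept but flagged ``valid=False``.
    """
    wide = means.pivot_table(index="feature_id", columns=["signal", "dose"],
                             values="mean", observed=True)
    control = wide.get((reference_signal, "none"))
    if control is None:
        raise ValueError(f"no {reference_signal!r} samples with dose 'none'")
    cv_both = (cvs[cvs["signal"] == "both"]
               .set_index("feature_id")["cv"].reindex(wide.index))
    if isinstance(ci_df, str) and ci_df == "auto":
        both = means[means["signal"] == "both"]
        df_val = float((both.groupby("feature_id")["n"].apply(
            lambda n: (n - 1).sum())).median()) if len(both) else None
    else:
        df_val = ci_df

    rows = []
    for dose in doses:
        x0 = control.to_numpy(dtype=float)
        xA = _column(wide, ("signalA", dose))
        xB = _column(wide, ("signalB", dose))
        xAB = _column(wide, ("both", dose))
        cv = cv_both.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dA = xA - x0
            dB = xB - x0
            pred_add = x0 + dA + dB
            pred_mult = xA * xB / x0
            sd = xAB * cv
            lo, hi = normal_interval(xAB, sd, ci_level, df_val)
        valid = (x0 > 0) & np.isfinite(xA) & np.isfinite(xB) & np.isfinite(xAB) \
            & np.isfinite(cv)
        rows.append(pd.DataFrame({
            "feature_id": wide.index, "dose": dose, "x0": x0, "dA": dA, "dB": dB,
            "xAB": xAB, "cv_both": cv, "ci_lo": lo, "ci_hi": hi,
            "pred_add": pred_add, "pred_mult": pred_mult, "valid": valid,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out[RESPONSE_COLUMNS]


def _column(wide: pd.DataFrame, key: tuple[str, str]) -> np.ndarray:
    if key in wide.columns:
        return wide[key].to_numpy(dtype=float)
    return np.full(len(wide), np.nan)


# ---------------------------------------------------------------------------
# Categorical classification

def classify_gene_table(responses: pd.DataFrame) -> pd.Series:
    """Six-way gene classification; interval endpoints are inclusive.

    sub_additive: both predictions above the CI; additive: only the
    additive prediction inside; between_add_mult: the CI sits strictly
    between the predictions; multiplicative: only the multiplicative
    prediction inside; super_multiplicative: both below the CI;
    ambiguous: both inside.  Invalid estimates get a missing category.
    """
    add_in = (responses["pred_add"] >= responses["ci_lo"]) & \
             (responses["pred_add"] <= responses["ci_hi"])
    mult_in = (responses["pred_mult"] >= responses["ci_lo"]) & \
              (responses["pred_mult"] <= responses["ci_hi"])
    add_above = responses["pred_add"] > responses["ci_hi"]
    mult_above = responses["pred_mult"] > responses["ci_hi"]
    add_below = responses["pred_add"] < responses["ci_lo"]
    mult_below = responses["pred_mult"] < responses["ci_lo"]

    cat = np.select(
        [add_above & mult_above,
         add_in & mult_in,
         add_in & mult_above,
         add_below & mult_above,
         add_below & mult_in,
         add_below & mult_below],
        ["sub_additive", "ambiguous", "additive", "between_add_mult",
         "multiplicative", "super_multiplicative"],
        default="ambiguous",
    )
    out = pd.Series(cat, index=responses.index, dtype="object")
    out[~responses["valid"].astype(bool)] = pd.NA
    return out


def classify_gene(r: dict | pd.Series) -> str | None:
    """Classify a single gene response estimate."""
    return _classify_one(r, classify_gene_table)


def classify_peak_table(responses: pd.DataFrame) -> pd.Series:
    """Three-way peak classification against the additive prediction only."""
    add_above = responses["pred_add"] > responses["ci_hi"]
    add_below = responses["pred_add"] < responses["ci_lo"]
    cat = np.select([add_above, add_below],
                    ["sub_additive", "super_additive"], default="additive")
    out = pd.Series(cat, index=responses.index, dtype="object")
    out[~responses["valid"].astype(bool)] = pd.NA
    return out


def classify_peak(r: dict | pd.Series) -> str | None:
    """Classify a single peak response estimate."""
    return _classify_one(r, classify_peak_table)


def _classify_one(r, table_fn) -> str | None:
    frame = pd.DataFrame([dict(r)])
    if "valid" not in frame:
        frame["valid"] = True
    val = table_fn(frame).iloc[0]
    return None if pd.isna(val) else str(val)
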