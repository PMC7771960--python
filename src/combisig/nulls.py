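"""Monte-Carlo nulls for the c and d statistics.

To ask whether the observed c-value histogram is consistent with purely
additive (or multiplicative) signal integration plus measurement noise,
each feature's four conditions are re-simulated from its fitted
folded-Gaussian noise model, with the combined-treatment mean pinned to
the perfectly additive or perfectly multiplicative prediction.  The
statistic is then recomputed from the simulated replicate means, giving a
null distribution per feature.  A two-component mixture (additive +
multiplicative, mixed at the observed categorical frequencies) is scaled
to the observed histogram at the bars abutting c = 0 and c = 1; the
residual after subtracting the scaled additive component locates the
secondary peak.  Sliding-window Poisson tail probabilities quantify
whether any histogram bin holds more mass than an all-additive world
would produce.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .response import compute_c, compute_d
from .synth import folded_normal


@dataclass
class SimulatedNull:
    mode: str                  # additive | multiplicative | mixture
    statistic: str             # c | d
    values: pd.DataFrame       # feature_id, dose, sim, value
    n_sims: int
    seed: int | None
    n_skipped: int


@dataclass
class ResidualFit:
    center: float
    width: float
    amplitude: float
    converged: bool
    degenerate: bool
    message: str = ""


# ---------------------------------------------------------------------------
# simulation

def _signal_cv_arrays(responses: pd.DataFrame, cvs: pd.DataFrame
                      ) -> dict[str, np.ndarray]:
    wide = cvs.pivot(index="feature_id", columns="signal", values="cv")
    wide = wide.reindex(responses["feature_id"])
    out = {}
    for sig in ("control", "signalA", "signalB", "both"):
        col = wide[sig] if sig in wide.columns else pd.Series(np.nan, index=wide.index)
        out[sig] = col.to_numpy(dtype=float)
    return out


def simulate_null(responses: pd.DataFrame, cvs: pd.DataFrame, mode: str,
                  n_sims: int, seed: int | None = None,
                  statistic: str = "c", n_draws: int = 3,
                  mixture_p_mult: dict[str, float] | None = None,
                  rng: np.random.Generator | None = None) -> SimulatedNull:
    """Simulate the c (or d) statistic under a noise-only null.

    Per feature and simulation, ``n_draws`` folded-Gaussian observations
    are drawn for control, signal A, signal B and the combined treatment,
    with the combined mean replaced by the additive or multiplicative
    prediction; the statistic is recomputed from the simulated means.  In
    mixture mode each (feature, dose) is assigned multiplicative with the
    dose-specific probability ``mixture_p_mult[dose]``.

    Features lacking a valid estimate or a finite CV are skipped and
    counted on the returned object.
    """
    if mode not in ("additive", "multiplicative", "mixture"):
        raise ValueError(f"unknown null mode {mode!r}")
    if mode == "mixture" and mixture_p_mult is None:
        raise ValueError("mixture mode needs mixture_p_mult")
    rng = rng if rng is not None else np.random.default_rng(seed)

    cv = _signal_cv_arrays(responses, cvs)
    usable = responses["valid"].to_numpy(dtype=bool)
    for sig in cv:
        usable &= np.isfinite(cv[sig])
    n_skipped = int((~usable).sum())
    resp = responses[usable].reset_index(drop=True)
    cv = {sig: arr[usable] for sig, arr in cv.items()}
    n = len(resp)

    x0 = resp["x0"].to_numpy(dtype=float)
    xA = x0 + resp["dA"].to_numpy(dtype=float)
    xB = x0 + resp["dB"].to_numpy(dtype=float)
    pred_add = resp["pred_add"].to_numpy(dtype=float)
    pred_mult = resp["pred_mult"].to_numpy(dtype=float)

    if mode == "additive":
        mu_both = np.broadcast_to(pred_add[:, None], (n, n_sims))
    elif mode == "multiplicative":
        mu_both = np.broadcast_to(pred_mult[:, None], (n, n_sims))
    else:
        p = resp["dose"].map(mixture_p_mult).to_numpy(dtype=float)
        take_mult = rng.random((n, n_sims)) < p[:, None]
        mu_both = np.where(take_mult, pred_mult[:, None], pred_add[:, None])

    def sim_means(mu: np.ndarray, cv_sig: np.ndarray) -> np.ndarray:
        mu_arr = np.asarray(mu, dtype=float)
        mu_b = mu_arr[:, None, None] if mu_arr.ndim == 1 else mu_arr[:, :, None]
        sd = np.abs(mu_b) * cv_sig[:, None, None]
        shape = (n, n_sims, n_draws)
        draws = folded_normal(rng, np.broadcast_to(mu_b, shape),
                              np.broadcast_to(sd, shape))
        return draws.mean(axis=2)

    m0 = sim_means(x0, cv["control"])
    mA = sim_means(xA, cv["signalA"])
    mB = sim_means(xB, cv["signalB"])
    mAB = sim_means(mu_both, cv["both"])

    if statistic == "c":
        value = compute_c(m0, mA - m0, mB - m0, mAB)
    elif statistic == "d":
        value = compute_d(mA + mB - m0, mAB)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    frame = pd.DataFrame({
        "feature_id": np.repeat(resp["feature_id"].to_numpy(), n_sims),
        "dose": np.repeat(resp["dose"].to_numpy(), n_sims),
        "sim": np.tile(np.arange(n_sims), n),
        "value": value.ravel()})
    return SimulatedNull(mode=mode, statistic=statistic, values=frame,
                         n_sims=n_sims, seed=seed, n_skipped=n_skipped)


def mixture_probabilities(categories: pd.Series | pd.DataFrame) -> dict[str, float]:
    """Dose-specific P(multiplicative) among additive+multiplicative calls.

    ``categories``: DataFrame with columns ``dose, category``.  Frequencies
    are renormalized over the two anchor categories only.
    """
    df = categories if isinstance(categories, pd.DataFrame) else categories.to_frame()
    out = {}
    for dose, grp in df.groupby("dose", observed=True):
        n_add = int((grp["category"] == "additive").sum())
        n_mult = int((grp["category"] == "multiplicative").sum())
        out[str(dose)] = n_mult / (n_add + n_mult) if (n_add + n_mult) else 0.5
    return out


# ---------------------------------------------------------------------------
# histograms

def base_histogram(values, width: float = 0.25,
                   value_range: tuple[float, float] = (-8.0, 8.0)
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping histogram with bin edges aligned at 0 (and hence 1
    for the default width).  Returns (left_edges, counts)."""
    lo = np.floor(value_range[0] / width) * width
    hi = np.ceil(value_range[1] / width) * width
    edges = np.round(np.arange(lo, hi + width / 2, width), 10)
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
    return edges[:-1], counts.astype(float)


def overlapping_histogram(values, width: float = 0.25, step: float = 0.125,
                          value_range: tuple[float, float] = (-8.0, 8.0)
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window counts: windows [l, l+width) with l on a step grid."""
    values = np.asarray(values, dtype=float)
    lo = np.floor(value_range[0] / step) * step
    hi = np.ceil(value_range[1] / step) * step
    lefts = np.round(np.arange(lo, hi - width + step / 2, step), 10)
    sorted_v = np.sort(values)
    lo_idx = np.searchsorted(sorted_v, lefts, side="left")
    hi_idx = np.searchsorted(sorted_v, lefts + width, side="left")
    return lefts, (hi_idx - lo_idx).astype(float)


def _abutting_indices(left_edges: np.ndarray, width: float) -> np.ndarray:
    """Indices of the four bars directly abutting c = 0 and c = 1."""
    targets = [-width, 0.0, 1.0 - width, 1.0]
    idx = []
    for t in targets:
        hit = np.where(np.isclose(left_edges, t))[0]
        if hit.size != 1:
            raise ValueError("histogram binning must place bin edges at 0 and 1")
        idx.append(hit[0])
    return np.asarray(idx)


def fit_mixture_scale(observed_counts: np.ndarray, simulated_counts: np.ndarray,
                      left_edges: np.ndarray, width: float = 0.25) -> float:
    """Least-squares scale between histograms at the bars abutting 0 and 1.

    Minimizes sum over the 4 bars of (observed - scale*simulated)^2, whose
    closed form is ``sum(o*s) / sum(s^2)``.
    """
    idx = _abutting_indices(np.asarray(left_edges), width)
    o = np.asarray(observed_counts, dtype=float)[idx]
    s = np.asarray(simulated_counts, dtype=float)[idx]
    denom = float(np.sum(s * s))
    if denom == 0.0:
        raise ValueError("all four simulated bars abutting 0 and 1 are zero")
    return float(np.sum(o * s) / denom)


def residual_secondary_peak(observed_counts: np.ndarray,
                            additive_counts: np.ndarray, scale: float,
                            left_edges: np.ndarray, width: float = 0.25,
                            fit_range: tuple[float, float] = (-4.0, 5.0)
                            ) -> ResidualFit:
    """Gaussian density fit to the residual histogram.

    The scaled additive component is subtracted from the observed counts
    and ``A*exp(-(x-mu)^2/(2*sigma^2))`` is fit to the residual at bin
    centers within ``fit_range``.  A residual indistinguishable from zero
    is returned as a degenerate fit rather than an error.
    """
    left_edges = np.asarray(left_edges, dtype=float)
    residual = (np.asarray(observed_counts, dtype=float)
                - scale * np.asarray(additive_counts, dtype=float))
    centers = left_edges + width / 2.0
    mask = (centers >= fit_range[0]) & (centers <= fit_range[1])
    x, y = centers[mask], residual[mask]

    amp0 = float(y.max(initial=0.0))
    if amp0 <= 0 or not np.any(y > 0):
        return ResidualFit(np.nan, np.nan, 0.0, converged=False,
                           degenerate=True, message="non-positive residual")
    mu0 = float(x[np.argmax(y)])

    def gaussian(xx, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((xx - mu) / sigma) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            gaussian, x, y, p0=(amp0, mu0, 0.5),
            bounds=((0.0, fit_range[0], 1e-3),
                    (np.inf, fit_range[1], fit_range[1] - fit_range[0])),
            maxfev=10000)
    except Exception as exc:
        return ResidualFit(np.nan, np.nan, np.nan, converged=False,
                           degenerate=False, message=f"no convergence: {exc}")
    amp, mu, sigma = (float(v) for v in popt)
    degenerate = amp < 1e-8 * max(1.0, float(np.abs(y).max()))
    return ResidualFit(center=mu, width=sigma, amplitude=amp,
                       converged=True, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Poisson sliding-window p-values

def poisson_tail(k: int, lam: float) -> float:
    """P(Poisson(lam) >= k); k = 0 gives 1, lam = 0 with k > 0 gives 0."""
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))

def poisson_bin_pvalues(observed_values, responses: pd.DataFrame,
                        cvs: pd.DataFrame, n_reps: int = 1000,
                        width: float = 0.25, step: float = 0.125,
                        value_range: tuple[float, float] = (-8.0, 8.0),
                        exclusion: tuple[float, float] = (-0.3, 0.3),
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Probability of each observed histogram bin under an all-additive null.

    ``n_reps`` additive simulations are run, each yielding one simulated c
    per feature.  The observed counts are scaled so their peak height at
    c = 0 (the two base bins abutting zero) matches the mean simulated
    peak height.  For each sliding window outside the exclusion zone the
    mean simulated count is the Poisson rate lambda, and
    ``p = P(Poisson(lambda) >= k)`` for the scaled observed count k
    (rounded to the nearest integer).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    null = simulate_null(responses, cvs, "additive", n_sims=n_reps,
                         statistic="c", rng=rng)
    sims = null.values.pivot(index="feature_id", columns="sim", values="value")

    base_edges, obs_base = base_histogram(observed_values, width, value_range)
    abut0 = [np.where(np.isclose(base_edges, -width))[0][0],
             np.where(np.isclose(base_edges, 0.0))[0][0]]
    sim_matrix = sims.to_numpy()

    # per-rep base histograms at the two bins abutting zero
    sim_base = np.stack([
        base_histogram(sim_matrix[:, j][np.isfinite(sim_matrix[:, j])],
                       width, value_range)[1]
        for j in range(sim_matrix.shape[1])])
    obs_height = float(obs_base[abut0].sum())
    sim_height = float(sim_base[:, abut0].sum(axis=1).mean())
    if obs_height == 0:
        raise ValueError("observed histogram has no mass at c = 0")
    scale = sim_height / obs_height

    lefts, obs_counts = overlapping_histogram(observed_values, width, step,
                                              value_range)
    sim_counts = np.stack([
        overlapping_histogram(sim_matrix[:, j][np.isfinite(sim_matrix[:, j])],
                              width, step, value_range)[1]
        for j in range(sim_matrix.shape[1])])
    lam = sim_counts.mean(axis=0)

    k = np.rint(obs_counts * scale).astype(int)
    p = np.array([poisson_tail(int(kk), float(ll)) for kk, ll in zip(k, lam)])
    flagged = (lam == 0) & (k > 0)

    out = pd.DataFrame({
        "bin_lo": lefts, "bin_hi": lefts + width,
        "observed": obs_counts, "observed_scaled": obs_counts * scale,
        "k": k, "lam": lam, "p": p, "zero_lambda_flag": flagged})
    keep = (out["bin_hi"] <= exclusion[0]) | (out["bin_lo"] >= exclusion[1])
    return out[keep].reset_index(drop=True)
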