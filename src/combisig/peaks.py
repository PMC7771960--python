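"""Differential accessibility peak calling with an empirical FDR grid.

Consensus peaks are fixed-width (one nucleosome, 150 bp) windows centered
on replicate summits supported by a majority of replicates; condition
peak sets are merged into a non-overlapping master set.  Fragment counts
are normalized by each sample's reads-in-peaks total relative to the
cross-sample average, so the grand total is conserved.

Differential calling scans a 50x50 grid of (minimum fold-change, minimum
count) thresholds, geometrically spaced.  At each cell, the number of
differential (peak, condition) calls among extra control conditions -
which differ from the reference only in starting cell density and hence
are true nulls - estimates the false-positive count, giving

    estimated FDR = n_conditions * mean FP per extra control
                    / total differential calls in experimental conditions.

Calls from every cell whose estimated FDR clears the threshold are
pooled; peaks within 250 bp are merged and a second, fixed-threshold pass
(fold-change >= 1.5, count >= 30) produces the final set with its pooled
FDR recomputed the same way.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (EXPERIMENTAL_SIGNALS, EXTRA_CONTROL_SIGNALS,
                     REFERENCE_SIGNAL)

log = logging.getLogger("combisig")


# ---------------------------------------------------------------------------
# consensus peaks

def consensus_peaks(summits_per_replicate: list[pd.DataFrame] | dict,
                    width: int = 150, min_support: int = 2) -> pd.DataFrame:
    """Majority-rule consensus peaks from per-replicate summit sets.

    Summits from different replicates whose ``width``-bp windows overlap
    (summit distance < width) are grouped by single linkage; groups seen
    in at least ``min_support`` distinct replicates emit one peak of
    ``width`` bp centered on the group's median summit.
    """
    if isinstance(summits_per_replicate, dict):
        items = sorted(summits_per_replicate.items())
    else:
        items = list(enumerate(summits_per_replicate, start=1))
    frames = []
    for rep, df in items:
        if df is None or len(df) == 0:
            log.warning("replicate %s has an empty summit set (zero support)", rep)
            continue
        frames.append(pd.DataFrame({"chrom": df["chrom"].astype(str),
                                    "pos": df["pos"].astype(int),
                                    "replicate": rep}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "summit", "support"])
    allsum = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    rows = []
    for chrom, grp in allsum.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        reps = grp["replicate"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= width) + 1
        for seg_pos, seg_rep in zip(np.split(pos, breaks), np.split(reps, breaks)):
            support = len(np.unique(seg_rep))
            if support < min_support:
                continue
            summit = int(np.median(seg_pos))
            start = summit - width // 2
            rows.append((chrom, start, start + width, summit, support))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit",
                                       "support"])


def build_master_consensus(per_condition_peaks: list[pd.DataFrame]
                           ) -> pd.DataFrame:
    """Union of condition peak sets with overlaps collapsed to one peak.

    Overlapping intervals (half-open) are collapsed to their spanning
    interval; the output is pairwise non-overlapping, sorted, and given
    stable ids.
    """
    nonempty = [p for p in per_condition_peaks if len(p)]
    if not nonempty:
        return pd.DataFrame(columns=["peak_id", "chrom", "start", "end", "summit"])
    allp = pd.concat(nonempty, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # overlap (half-open intervals)
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["summit"] = (out["start"] + out["end"]) // 2
    out.insert(0, "peak_id", [f"mpeak{i:05d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# normalization

def normalize_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize a peak x sample count matrix.

    Each sample is divided by ``total_s / mean(total)``; afterwards every
    sample's reads-in-peaks total equals the grand mean and the grand
    total is conserved.
    """
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"sample(s) with zero reads in peaks: {bad}")
    scale = totals / totals.mean()
    return raw / scale


def condition_means(norm_counts: pd.DataFrame, annotations: pd.DataFrame
                    ) -> pd.DataFrame:
    """Mean normalized counts per (signal, dose) condition.

    Returns a peak x condition frame with MultiIndex columns.
    """
    sample_to_cond = annotations.set_index("sample_id")[["signal", "dose"]]
    cols = norm_counts.columns
    key = pd.MultiIndex.from_frame(sample_to_cond.loc[cols])
    grouped = norm_counts.T.groupby(key).mean().T
    grouped.columns = pd.MultiIndex.from_tuples(grouped.columns,
                                                names=["signal", "dose"])
    return grouped


# ---------------------------------------------------------------------------
# FDR grid

def geometric_steps(lo: float, hi: float, n: int) -> np.ndarray:
    """n geometrically spaced values inclusive of both endpoints."""
    return lo * (hi / lo) ** (np.arange(n) / (n - 1))


@dataclass
class FdrGrid:
    fc_thresholds: np.ndarray
    count_thresholds: np.ndarray
    n_differential: np.ndarray       # experimental calls per cell
    fp_estimate: np.ndarray          # mean extra-control calls per cell
    fdr: np.ndarray                  # NaN where 0 calls (0/0 undefined)
    n_conditions: int
    peak_ids: np.ndarray
    conditions: list[tuple[str, str]]
    exp_fc: np.ndarray               # peak x condition fold changes
    exp_maxc: np.ndarray             # peak x condition max(mean, ref mean)
    ctl_fc: np.ndarray               # peak x extra-control
    ctl_maxc: np.ndarray
    control_names: list[str]


def _pair_stats(cond: np.ndarray, ref: np.ndarray, pseudocount: float
                ) -> tuple[np.ndarray, np.ndarray]:
    a = cond + pseudocount
    b = ref + pseudocount
    fc = np.maximum(a / b, b / a)
    return fc, np.maximum(cond, ref)


def _suffix_counts(fc: np.ndarray, maxc: np.ndarray, fc_thr: np.ndarray,
                   cnt_thr: np.ndarray) -> np.ndarray:
    """N[i, j] = number of entries with fc >= fc_thr[i] and maxc >= cnt_thr[j]."""
    fi = np.searchsorted(fc_thr, fc.ravel(), side="right") - 1
    ci = np.searchsorted(cnt_thr, maxc.ravel(), side="right") - 1
    keep = (fi >= 0) & (ci >= 0)
    hist = np.zeros((len(fc_thr), len(cnt_thr)))
    np.add.at(hist, (fi[keep], ci[keep]), 1.0)
    return _suffix2d(hist)


def _suffix2d(hist: np.ndarray) -> np.ndarray:
    s = np.flip(np.cumsum(np.flip(hist, axis=0), axis=0), axis=0)
    return np.flip(np.cumsum(np.flip(s, axis=1), axis=1), axis=1)


def fdr_grid(norm_counts: pd.DataFrame, annotations: pd.DataFrame,
             fc_grid: tuple[float, float, int] = (1.1, 10.0, 50),
             count_grid: tuple[float, float, int] = (10.0, 237.0, 50),
             pseudocount: float = 1.0,
             reference_signal: str = REFERENCE_SIGNAL) -> FdrGrid:
    """Estimated FDR for every (min fold-change, min count) threshold pair.

    A (peak, condition) pair is differential at a cell iff its fold change
    vs the reference control is at least the cell's fold-change threshold
    and the larger of the two means is at least the count threshold.
    """
    means = condition_means(norm_counts, annotations)
    if (reference_signal, "none") not in means.columns:
        raise ValueError(f"no {reference_signal!r} condition in annotations")
    ref = means[(reference_signal, "none")].to_numpy()

    conditions = [c for c in means.columns if c[0] in EXPERIMENTAL_SIGNALS]
    controls = [c for c in means.columns if c[0] in EXTRA_CONTROL_SIGNALS]
    if not controls:
        raise ValueError("at least one extra control condition is required")

    exp_fc = np.empty((len(means), len(conditions)))
    exp_maxc = np.empty_like(exp_fc)
    for j, cond in enumerate(conditions):
        exp_fc[:, j], exp_maxc[:, j] = _pair_stats(
            means[cond].to_numpy(), ref, pseudocount)
    ctl_fc = np.empty((len(means), len(controls)))
    ctl_maxc = np.empty_like(ctl_fc)
    for j, cond in enumerate(controls):
        ctl_fc[:, j], ctl_maxc[:, j] = _pair_stats(
            means[cond].to_numpy(), ref, pseudocount)

    fc_thr = geometric_steps(*fc_grid)
    cnt_thr = geometric_steps(*count_grid)
    n_diff = _suffix_counts(exp_fc, exp_maxc, fc_thr, cnt_thr)
    fp_each = [_suffix_counts(ctl_fc[:, [k]], ctl_maxc[:, [k]], fc_thr, cnt_thr)
               for k in range(len(controls))]
    fp = np.mean(fp_each, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = len(conditions) * fp / n_diff
    fdr = np.where(n_diff > 0, fdr, np.nan)
    return FdrGrid(fc_thresholds=fc_thr, count_thresholds=cnt_thr,
                   n_differential=n_diff, fp_estimate=fp, fdr=fdr,
                   n_conditions=len(conditions),
                   peak_ids=np.asarray(norm_counts.index),
                   conditions=list(conditions), exp_fc=exp_fc,
                   exp_maxc=exp_maxc, ctl_fc=ctl_fc, ctl_maxc=ctl_maxc,
                   control_names=[c[0] for c in controls])


@dataclass
class DifferentialCalls:
    calls: pd.DataFrame              # peak_id, signal, dose
    pooled_fdr: float
    n_false_positive_estimate: float
    n_qualifying_cells: int
    round: int = 1


def _region_mask(values_fc: np.ndarray, values_cnt: np.ndarray,
                 fc_thr: np.ndarray, cnt_thr: np.ndarray,
                 qualifying: np.ndarray) -> np.ndarray:
    """True where a pair satisfies at least one qualifying cell's thresholds."""
    reach = np.maximum.accumulate(np.maximum.accumulate(
        qualifying.astype(bool), axis=0), axis=1)
    fi = np.searchsorted(fc_thr, values_fc, side="right") - 1
    ci = np.searchsorted(cnt_thr, values_cnt, side="right") - 1
    ok = (fi >= 0) & (ci >= 0)
    out = np.zeros(values_fc.shape, dtype=bool)
    out[ok] = reach[fi[ok], ci[ok]]
    return out


def call_differential_peaks(grid: FdrGrid, cell_fdr_threshold: float = 0.0025
                            ) -> DifferentialCalls:
    """Pool differential calls from every grid cell under the FDR threshold.

    The pooled estimated FDR is recomputed on the pooled call set: the
    same qualifying region is applied to the extra controls and the FDR
    formula evaluated on the union counts.
    """
    qualifying = np.isfinite(grid.fdr) & (grid.fdr < cell_fdr_threshold)
    n_cells = int(qualifying.sum())
    if n_cells == 0:
        log.warning("no grid cell meets the FDR threshold %g", cell_fdr_threshold)
        empty = pd.DataFrame(columns=["peak_id", "signal", "dose"])
        return DifferentialCalls(empty, float("nan"), 0.0, 0)

    exp_mask = _region_mask(grid.exp_fc, grid.exp_maxc, grid.fc_thresholds,
                            grid.count_thresholds, qualifying)
    ctl_mask = _region_mask(grid.ctl_fc, grid.ctl_maxc, grid.fc_thresholds,
                            grid.count_thresholds, qualifying)

    pk_idx, cond_idx = np.nonzero(exp_mask)
    calls = pd.DataFrame({
        "peak_id": grid.peak_ids[pk_idx],
        "signal": [grid.conditions[j][0] for j in cond_idx],
        "dose": [grid.conditions[j][1] for j in cond_idx]})
    fp = float(ctl_mask.sum(axis=0).mean())
    total = int(exp_mask.sum())
    pooled = grid.n_conditions * fp / total if total else float("nan")
    if total and fp == 0.0:
        # the FP estimator's resolution is 1/n_controls calls; a zero here
        # bounds the FDR near n_conditions/(n_controls * total), it does
        # not certify zero
        log.warning("pooled FP estimate saturated at zero over %d calls; "
                    "estimate unreliable below ~%.2g", total,
                    grid.n_conditions / (grid.ctl_fc.shape[1] * total))
    return DifferentialCalls(calls, pooled, fp, n_cells)


# ---------------------------------------------------------------------------
# merging and the second round

def merge_peaks(peaks: pd.DataFrame, merge_distance: int = 250) -> pd.DataFrame:
    """Merge peaks within ``merge_distance`` bp (boundary inclusive).

    Returns merged intervals with a ``members`` column listing the
    constituent peak ids.
    """
    if len(peaks) == 0:
        return pd.DataFrame(columns=["peak_id", "chrom", "start", "end", "members"])
    srt = peaks.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, grp in srt.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        ids = grp["peak_id"].to_numpy()
        cur = [ids[0]]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e, pid in zip(starts[1:], ends[1:], ids[1:]):
            if s - cur_e <= merge_distance:
                cur_e = max(cur_e, int(e))
                cur.append(pid)
            else:
                rows.append((chrom, cur_s, cur_e, list(cur)))
                cur, cur_s, cur_e = [pid], int(s), int(e)
        rows.append((chrom, cur_s, cur_e, list(cur)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "members"])
    out.insert(0, "peak_id", [f"merged{i:05d}" for i in range(len(out))])
    return out


def merge_and_recall(round1: DifferentialCalls, peaks: pd.DataFrame,
                     norm_counts: pd.DataFrame, annotations: pd.DataFrame,
                     merge_distance: int = 250, min_fc: float = 1.5,
                     min_count: float = 30.0, pseudocount: float = 1.0,
                     reference_signal: str = REFERENCE_SIGNAL
                     ) -> tuple[pd.DataFrame, DifferentialCalls]:
    """Merge round-1 peaks and re-call at fixed thresholds.

    Counts are re-aggregated (summed) over each merged interval's member
    peaks; the pooled estimated FDR of the final set is recomputed from
    the extra controls at the same fixed thresholds.

    Returns (merged peak table, round-2 calls).
    """
    called_ids = round1.calls["peak_id"].unique()
    sub = peaks[peaks["peak_id"].isin(called_ids)]
    merged = merge_peaks(sub, merge_distance)
    agg = pd.DataFrame(
        {row["peak_id"]: norm_counts.loc[row["members"]].sum(axis=0)
         for _, row in merged.iterrows()}).T
    if len(agg) == 0:
        empty = pd.DataFrame(columns=["peak_id", "signal", "dose"])
        return merged, DifferentialCalls(empty, float("nan"), 0.0, 0, round=2)
    agg.index.name = "peak_id"

    means = condition_means(agg, annotations)
    ref = means[(reference_signal, "none")].to_numpy()
    conditions = [c for c in means.columns if c[0] in EXPERIMENTAL_SIGNALS]
    controls = [c for c in means.columns if c[0] in EXTRA_CONTROL_SIGNALS]

    def called(cond):
        fc, maxc = _pair_stats(means[cond].to_numpy(), ref, pseudocount)
        return (fc >= min_fc) & (maxc >= min_count)

    exp_mask = np.column_stack([called(c) for c in conditions])
    ctl_mask = np.column_stack([called(c) for c in controls]) if controls \
        else np.zeros((len(means), 0), dtype=bool)

    pk_idx, cond_idx = np.nonzero(exp_mask)
    calls = pd.DataFrame({
        "peak_id": np.asarray(agg.index)[pk_idx],
        "signal": [conditions[j][0] for j in cond_idx],
        "dose": [conditions[j][1] for j in cond_idx]})
    fp = float(ctl_mask.sum(axis=0).mean()) if ctl_mask.size else 0.0
    total = int(exp_mask.sum())
    pooled = len(conditions) * fp / total if total else float("nan")
    return merged, DifferentialCalls(calls, pooled, fp, 0, round=2)
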