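"""Relating peak behavior to gene behavior.

Peaks are linked to genes whose TSS lies within a window (100 kb by
default) of the peak midpoint.  Per gene-category averages of nearby
sub-additive/additive/super-additive peaks carry percentile-bootstrap
confidence intervals resampled over genes.  A peak responds exclusively
to one signal when that signal's accessibility change is at least 90% of
the summed absolute changes from both signals (a 9x major/minor ratio).
Motif matches are collapsed into factor groups (the maximum member count
per peak), densities are per 150 bp of peak width, and the dual-motif
null shuffles grouped matches within each peak class while preserving
every peak's total match count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources as importlib_resources

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("combisig")


# ---------------------------------------------------------------------------
# motif group resource

def load_motif_groups(path=None) -> pd.DataFrame:
    """Motif -> group -> dominance-class table (editable TSV resource)."""
    if path is None:
        ref = importlib_resources.files("combisig") / "resources/motif_groups.tsv"
        with importlib_resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if df["motif"].duplicated().any():
        dup = df.loc[df["motif"].duplicated(), "motif"].iloc[0]
        raise ValueError(f"motif {dup!r} belongs to more than one group")
    return df


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(values: np.ndarray, n_boot: int, level: float,
                 rng: np.random.Generator, stat: str = "mean"
                 ) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean or median.  Returns (point, lo, hi)."""
    values = np.asarray(values, dtype=float)
    fn = np.mean if stat == "mean" else np.median
    point = float(fn(values))
    if values.size == 0:
        return float("nan"), float("nan"), float("nan")
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    reps = fn(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


# ---------------------------------------------------------------------------
# peak-gene links

def link_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                        window_bp: int = 100_000) -> pd.DataFrame:
    """Links where |TSS - peak midpoint| <= window (boundary inclusive).

    Genes without a TSS annotation are skipped with a log message.
    """
    usable = genes.dropna(subset=["tss", "chrom"])
    if len(usable) < len(genes):
        log.warning("skipped %d gene(s) without a TSS annotation",
                    len(genes) - len(usable))
    rows = []
    mid_all = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    for chrom, g in usable.groupby("chrom", sort=True):
        sel = peaks["chrom"] == chrom
        if not sel.any():
            continue
        mids = mid_all[sel.to_numpy()]
        pids = peaks.loc[sel, "peak_id"].to_numpy()
        order = np.argsort(mids)
        mids_s, pids_s = mids[order], pids[order]
        for gene_id, tss in zip(g["gene_id"], g["tss"].astype(int)):
            lo = np.searchsorted(mids_s, tss - window_bp, side="left")
            hi = np.searchsorted(mids_s, tss + window_bp, side="right")
            for k in range(lo, hi):
                rows.append((gene_id, pids_s[k], abs(int(mids_s[k]) - tss)))
    out = pd.DataFrame(rows, columns=["gene_id", "peak_id", "distance"])
    out["within_window"] = out["distance"] <= window_bp
    return out


def peak_class_counts_by_gene_category(
        links: pd.DataFrame, peak_categories: pd.DataFrame,
        gene_categories: pd.DataFrame, n_boot: int = 10_000,
        ci_level: float = 0.90, rng: np.random.Generator | None = None
        ) -> pd.DataFrame:
    """Mean nearby peaks per gene, split by gene and peak category.

    ``peak_categories``: peak_id, category; ``gene_categories``: gene_id,
    category.  Genes with no linked peak of a class count as zero; the CI
    is a percentile bootstrap over genes.  Empty gene categories are
    omitted (noted in the log).
    """
    rng = rng if rng is not None else np.random.default_rng()
    linked = links.merge(peak_categories.rename(
        columns={"category": "peak_category"}), on="peak_id", how="left")
    rows = []
    for gcat, genes_in_cat in gene_categories.groupby("category",
                                                      observed=True)["gene_id"]:
        gene_list = genes_in_cat.to_numpy()
        if gene_list.size == 0:
            log.warning("gene category %r is empty; row omitted", gcat)
            continue
        sub = linked[linked["gene_id"].isin(gene_list)]
        for pcat in sorted(peak_categories["category"].dropna().unique()):
            per_gene = (sub[sub["peak_category"] == pcat]
                        .groupby("gene_id").size()
                        .reindex(gene_list, fill_value=0).to_numpy(dtype=float))
            mean, lo, hi = bootstrap_ci(per_gene, n_boot, ci_level, rng)
            rows.append((gcat, pcat, mean, lo, hi, gene_list.size))
    return pd.DataFrame(rows, columns=["gene_category", "peak_category",
                                       "mean_peaks_per_gene", "ci_lo", "ci_hi",
                                       "n_genes"])


# ---------------------------------------------------------------------------
# signal-exclusive peaks

def label_exclusive_peaks(peak_responses: pd.DataFrame,
                          threshold: float = 0.9) -> pd.DataFrame:
    """Label peaks whose response is dominated by one signal.

    major_fraction = max(|dA|, |dB|) / (|dA| + |dB|); a peak is
    A_dominant or B_dominant iff the fraction is at least ``threshold``
    (>= 0.9 is the 9x major/minor criterion), otherwise shared.  Peaks
    with no response at all are left unlabeled.
    """
    dA = peak_responses["dA"].to_numpy(dtype=float)
    dB = peak_responses["dB"].to_numpy(dtype=float)
    denom = np.abs(dA) + np.abs(dB)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.maximum(np.abs(dA), np.abs(dB)) / denom
    label = np.where(denom == 0, None,
                     np.where(frac < threshold, "shared",
                              np.where(np.abs(dA) >= np.abs(dB),
                                       "A_dominant", "B_dominant")))
    out = peak_responses[["feature_id", "dose"]].copy()
    out = out.rename(columns={"feature_id": "peak_id"})
    out["major_fraction"] = np.where(denom == 0, np.nan, frac)
    out["label"] = label
    return out


def dual_dominant_gene_fraction(links: pd.DataFrame, labels: pd.DataFrame,
                                gene_categories: pd.DataFrame,
                                n_boot: int = 10_000, ci_level: float = 0.90,
                                rng: np.random.Generator | None = None
                                ) -> pd.DataFrame:
    """Fraction of genes with >=1 A-dominant and >=1 B-dominant peak nearby."""
    rng = rng if rng is not None else np.random.default_rng()
    tagged = links.merge(labels[["peak_id", "label"]], on="peak_id", how="left")
    has = tagged.pivot_table(index="gene_id", columns="label",
                             values="peak_id", aggfunc="count").fillna(0)
    rows = []
    for gcat, genes_in_cat in gene_categories.groupby("category",
                                                      observed=True)["gene_id"]:
        gene_list = genes_in_cat.to_numpy()
        if gene_list.size == 0:
            continue
        a = (has["A_dominant"].reindex(gene_list, fill_value=0)
             if "A_dominant" in has else pd.Series(0, index=gene_list))
        b = (has["B_dominant"].reindex(gene_list, fill_value=0)
             if "B_dominant" in has else pd.Series(0, index=gene_list))
        dual = ((a > 0) & (b > 0)).to_numpy(dtype=float)
        frac, lo, hi = bootstrap_ci(dual, n_boot, ci_level, rng)
        rows.append((gcat, frac, lo, hi, gene_list.size))
    return pd.DataFrame(rows, columns=["gene_category", "fraction",
                                       "ci_lo", "ci_hi", "n_genes"])


# ---------------------------------------------------------------------------
# motif analyses

def collapse_to_groups(matches: pd.DataFrame, groups: pd.DataFrame
                       ) -> pd.DataFrame:
    """Peak x group matrix: a group's count is the max over member motifs.

    Similar position-weight matrices make the same genomic site match
    several members; the maximum avoids over-counting.
    """
    out = {}
    for group, members in groups.groupby("group")["motif"]:
        present = [m for m in members if m in matches.columns]
        if present:
            out[group] = matches[present].max(axis=1)
    return pd.DataFrame(out, index=matches.index)


def motif_density(peaks: pd.DataFrame, matches: pd.DataFrame,
                  groups: pd.DataFrame, n_boot: int = 1000,
                  ci_level: float = 0.90,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Grouped motif matches per 150 bp of peak, by peak category.

    ``peaks`` needs peak_id, start, end, category.  Densities are
    per-peak ``group_count / (width / 150)``; the per-class mean carries
    a percentile-bootstrap CI over peaks.  A ``total`` row per class sums
    all groups.
    """
    rng = rng if rng is not None else np.random.default_rng()
    widths = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
    if (widths <= 0).any():
        bad = peaks.loc[widths <= 0, "peak_id"].iloc[0]
        raise ValueError(f"zero-width peak {bad!r}")
    grouped = collapse_to_groups(matches, groups).reindex(peaks["peak_id"])
    per150 = grouped.to_numpy(dtype=float) / (widths[:, None] / 150.0)
    cats = peaks["category"].to_numpy()

    rows = []
    for cat in pd.unique(cats[pd.notna(cats)]):
        sel = cats == cat
        for j, group in enumerate(grouped.columns):
            mean, lo, hi = bootstrap_ci(per150[sel, j], n_boot, ci_level, rng)
            rows.append((cat, group, mean, lo, hi, int(sel.sum())))
        tot = per150[sel].sum(axis=1)
        mean, lo, hi = bootstrap_ci(tot, n_boot, ci_level, rng)
        rows.append((cat, "total", mean, lo, hi, int(sel.sum())))
    return pd.DataFrame(rows, columns=["peak_category", "group", "density",
                                       "ci_lo", "ci_hi", "n_peaks"])


@dataclass
class ShuffleNull:
    per_class: pd.DataFrame     # category, observed, null_mean, p5, p95, p
    n_shuffles: int
    null_fractions: dict[str, np.ndarray]


def dual_motif_shuffle_null(peaks: pd.DataFrame, matches: pd.DataFrame,
                            groups: pd.DataFrame, n_shuffles: int = 1000,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None
                            ) -> ShuffleNull:
    """Null for dual-motif (RA-dominant + TGFB-dominant) co-occurrence.

    Within each peak category, the grouped motif matches are pooled and
    redistributed uniformly at random with every peak keeping its
    original total number of grouped matches; after each shuffle the
    fraction of peaks carrying at least one RA-dominant and at least one
    TGFB-dominant group match is recorded.  The empirical p value is
    two-sided with an add-one correction.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    grouped = collapse_to_groups(matches, groups).reindex(peaks["peak_id"])
    dominance = groups.drop_duplicates("group").set_index("group")["dominance"]
    group_names = list(grouped.columns)
    ra_cols = [j for j, g in enumerate(group_names)
               if dominance.get(g) == "RA_dominant"]
    tg_cols = [j for j, g in enumerate(group_names)
               if dominance.get(g) == "TGFB_dominant"]

    rows, null_store = [], {}
    for cat in pd.unique(peaks["category"].dropna()):
        sel = (peaks["category"] == cat).to_numpy()
        counts = grouped.to_numpy(dtype=int)[sel]
        n_peaks = counts.shape[0]
        if n_peaks < 2:
            log.warning("peak category %r has < 2 peaks; null undefined", cat)
            continue
        totals = counts.sum(axis=1)
        tokens = np.repeat(np.arange(counts.shape[1]),
                           counts.sum(axis=0))  # group label per match
        bounds = np.concatenate([[0], np.cumsum(totals)])

        def dual_fraction(mat: np.ndarray) -> float:
            has_ra = mat[:, ra_cols].sum(axis=1) > 0 if ra_cols else \
                np.zeros(mat.shape[0], bool)
            has_tg = mat[:, tg_cols].sum(axis=1) > 0 if tg_cols else \
                np.zeros(mat.shape[0], bool)
            return float(np.mean(has_ra & has_tg))

        observed = dual_fraction(counts)
        nulls = np.empty(n_shuffles)
        n_groups = counts.shape[1]
        for s in range(n_shuffles):
            perm = rng.permutation(tokens)
            flat = np.zeros((n_peaks, n_groups), dtype=int)
            peak_of_token = np.repeat(np.arange(n_peaks), totals)
            np.add.at(flat, (peak_of_token, perm), 1)
            assert (flat.sum(axis=1) == totals).all()  # totals conserved
            nulls[s] = dual_fraction(flat)
        p_low = (1 + np.sum(nulls <= observed)) / (n_shuffles + 1)
        p_high = (1 + np.sum(nulls >= observed)) / (n_shuffles + 1)
        p = min(1.0, 2.0 * min(p_low, p_high))
        rows.append((cat, observed, float(nulls.mean()),
                     float(np.percentile(nulls, 5)),
                     float(np.percentile(nulls, 95)), p, n_peaks))
        null_store[str(cat)] = nulls
    per_class = pd.DataFrame(rows, columns=["peak_category", "observed",
                                            "null_mean", "p5", "p95", "p",
                                            "n_peaks"])
    return ShuffleNull(per_class=per_class, n_shuffles=n_shuffles,
                       null_fractions=null_store)


def motif_enrichment_score(matches: pd.DataFrame, norm_counts: pd.DataFrame,
                           annotations: pd.DataFrame, condition_signal: str,
                           reference_signal: str = "control") -> pd.Series:
    """Percentage change in accessibility at motif-containing peaks.

    For each motif, the mean normalized fragment count over all peaks
    containing the motif, pooling every dose and replicate of
    ``condition_signal``, is compared with the same mean over reference
    samples: ``score = (cond - ref) / ref``.  Motifs contained in no peak
    get NaN (logged).
    """
    annot = annotations.set_index("sample_id")
    cond_samples = [s for s in norm_counts.columns
                    if annot.loc[s, "signal"] == condition_signal]
    ref_samples = [s for s in norm_counts.columns
                   if annot.loc[s, "signal"] == reference_signal]
    if not cond_samples or not ref_samples:
        raise ValueError("condition or reference has no samples")
    scores = {}
    common = matches.index.intersection(norm_counts.index)
    matches = matches.loc[common]
    for motif in matches.columns:
        carriers = matches.index[matches[motif] > 0]
        if len(carriers) == 0:
            log.warning("motif %s matches no peak; score undefined", motif)
            scores[motif] = np.nan
            continue
        cond_mean = norm_counts.loc[carriers, cond_samples].to_numpy().mean()
        ref_mean = norm_counts.loc[carriers, ref_samples].to_numpy().mean()
        scores[motif] = (cond_mean - ref_mean) / ref_mean
    return pd.Series(scores, name=f"score_{condition_signal}")


def motif_conditional_d(matches: pd.DataFrame, d_records: pd.DataFrame,
                        motif: str, n_boot: int = 1000, ci_level: float = 0.90,
                        rng: np.random.Generator | None = None
                        ) -> tuple[float, float, float]:
    """Median d over peaks containing ``motif``, with a bootstrap CI.

    ``d_records``: peak_id, d (one dose).  Returns (median, lo, hi);
    all-NaN if no containing peak has a d value.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if motif not in matches.columns:
        raise KeyError(f"unknown motif {motif!r}")
    carriers = set(matches.index[matches[motif] > 0])
    vals = d_records.loc[d_records["peak_id"].isin(carriers), "d"].dropna()
    if vals.empty:
        return float("nan"), float("nan"), float("nan")
    return bootstrap_ci(vals.to_numpy(), n_boot, ci_level, rng, stat="median")


# ---------------------------------------------------------------------------
# Welch's t-test

def welch_test(group1, group2) -> float:
    """Two-sided Welch unequal-variances t-test p value.

    No multiple-comparison correction is applied anywhere downstream.
    Returns NaN when either group has fewer than 2 values.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        return float("nan")
    if np.var(g1) == 0 and np.var(g2) == 0:
        return 1.0 if np.mean(g1) == np.mean(g2) else 0.0
    return float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
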