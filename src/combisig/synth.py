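"""Synthetic datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:
per-feature folded-Gaussian replicate noise whose coefficient of
variation is shared across the doses of a signal, individual-signal
effects that are positive at every dose (the upregulated regime the c/d
statistics are defined for), a configurable ground-truth c per gene and
d per peak, two extra control conditions drawn from the identical control
distribution (so every differential call against them is a false positive
by construction), a toy single-chromosome genome layout, and per-peak
motif-match counts with optional within-motif clustering.

Gene means per dose: control x0; A: x0+dA; B: x0+dB;
both: x0 + dA + dB + c_true*dA*dB/x0.  Peak combined means use the
d parameterization: (x0+dA+dB)*(1+d_true).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import (EXTRA_CONTROL_SIGNALS, TREATMENT_DOSES, SynthConfig)
from .io import Dataset

log = logging.getLogger("combisig")

CONDITION_SIGNALS = ("control", "signalA", "signalB", "both")


# ---------------------------------------------------------------------------
# helpers

def _loguniform(rng: np.random.Generator, lo: float, hi: float, size) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def folded_normal(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray,
                  size=None) -> np.ndarray:
    """|Normal(mean, sd^2)| -- the folded Gaussian used for all draws."""
    return np.abs(rng.normal(mean, sd, size=size))


def make_annotations(n_replicates: int, extra_controls: bool,
                     prefix: str = "s") -> pd.DataFrame:
    """Sample sheet: control (dose none), each signal x dose, replicates."""
    rows = []
    signals = ["control"] + (list(EXTRA_CONTROL_SIGNALS) if extra_controls else [])
    for sig in signals:
        for rep in range(1, n_replicates + 1):
            rows.append((f"{prefix}_{sig}_r{rep}", sig, "none", rep))
    for sig in ("signalA", "signalB", "both"):
        for dose in TREATMENT_DOSES:
            for rep in range(1, n_replicates + 1):
                rows.append((f"{prefix}_{sig}_{dose}_r{rep}", sig, dose, rep))
    return pd.DataFrame(rows, columns=["sample_id", "signal", "dose", "replicate"])


def _condition_means(x0: np.ndarray, dA: np.ndarray, dB: np.ndarray,
                     interaction: np.ndarray) -> dict[tuple[str, str], np.ndarray]:
    """Mean of every (signal, dose) condition; dA/dB are (n, n_doses)."""
    means: dict[tuple[str, str], np.ndarray] = {("control", "none"): x0}
    for j, dose in enumerate(TREATMENT_DOSES):
        means[("signalA", dose)] = x0 + dA[:, j]
        means[("signalB", dose)] = x0 + dB[:, j]
        means[("both", dose)] = x0 + dA[:, j] + dB[:, j] + interaction[:, j]
    return means


def _draw_long(rng: np.random.Generator, annotations: pd.DataFrame,
               means: dict[tuple[str, str], np.ndarray],
               cv: dict[str, np.ndarray], feature_ids: pd.Index,
               value_name: str) -> pd.DataFrame:
    """Replicate draws for every sample; extra controls reuse the control mean."""
    frames = []
    for _, row in annotations.iterrows():
        sig = row["signal"]
        base_sig = "control" if sig.startswith("control") else sig
        mu = means[(base_sig, "none" if base_sig == "control" else row["dose"])]
        sd = mu * cv[base_sig]
        values = folded_normal(rng, mu, sd)
        frames.append(pd.DataFrame({
            "feature_id": feature_ids, "sample_id": row["sample_id"],
            value_name: values}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression

def generate_expression_dataset(cfg: SynthConfig,
                                rng: np.random.Generator | None = None
                                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(expression long table, sample annotations, ground-truth genes).

    Ground truth columns: gene_id, truth_x0, truth_dA_<dose>,
    truth_dB_<dose>, truth_c, truth_cv_<signal>.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n)])
    x0 = _loguniform(rng, *cfg.gene_baseline_range, n)
    ratio_a = _loguniform(rng, *cfg.delta_ratio_range, n)
    ratio_b = _loguniform(rng, *cfg.delta_ratio_range, n)
    mult = np.asarray(cfg.dose_multipliers)
    dA = x0[:, None] * ratio_a[:, None] * mult[None, :]
    dB = x0[:, None] * ratio_b[:, None] * mult[None, :]

    weights = np.array([w for w, _, _ in cfg.c_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    c_means = np.array([m for _, m, _ in cfg.c_mixture])
    c_sds = np.array([s for _, _, s in cfg.c_mixture])
    c_true = rng.normal(c_means[comp], c_sds[comp])

    interaction = c_true[:, None] * dA * dB / x0[:, None]
    mu_both = x0[:, None] + dA + dB + interaction
    ok = (mu_both > 0).all(axis=1)
    if not ok.all():
        log.warning("rejected %d gene(s) whose combined mean went negative "
                    "under extreme c_true", int((~ok).sum()))
    gene_ids, x0, dA, dB, c_true, interaction = (
        gene_ids[ok], x0[ok], dA[ok], dB[ok], c_true[ok], interaction[ok])

    cv = {sig: rng.uniform(*cfg.cv_range, size=ok.sum())
          for sig in CONDITION_SIGNALS}
    annotations = make_annotations(cfg.n_replicates, extra_controls=False,
                                   prefix="rna")
    means = _condition_means(x0, dA, dB, interaction)
    expression = _draw_long(rng, annotations, means, cv, gene_ids, "tpm")
    expression = expression.rename(columns={"feature_id": "gene_id"})

    truth = pd.DataFrame({"gene_id": gene_ids, "truth_x0": x0, "truth_c": c_true})
    for j, dose in enumerate(TREATMENT_DOSES):
        truth[f"truth_dA_{dose}"] = dA[:, j]
        truth[f"truth_dB_{dose}"] = dB[:, j]
    for sig in CONDITION_SIGNALS:
        truth[f"truth_cv_{sig}"] = cv[sig]
    return expression, annotations, truth


def generate_de_table(expression: pd.DataFrame, annotations: pd.DataFrame
                      ) -> pd.DataFrame:
    """Surrogate differential-expression table for the combined treatment.

    A stand-in for an external DE fit, computed from the synthetic
    replicates: per (gene, dose), log2 fold-change of combined vs control
    means and a Welch-test p value, BH-adjusted within each dose.
    """
    annot = annotations.set_index("sample_id")
    merged = expression.merge(annotations, on="sample_id")
    ctrl = merged[merged["signal"] == "control"].pivot(
        index="gene_id", columns="replicate", values="tpm")
    rows = []
    for dose in TREATMENT_DOSES:
        both = merged[(merged["signal"] == "both") & (merged["dose"] == dose)]
        both = both.pivot(index="gene_id", columns="replicate", values="tpm")
        both = both.reindex(ctrl.index)
        t, p = stats.ttest_ind(both.to_numpy(), ctrl.to_numpy(), axis=1,
                               equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        eps = 1e-9
        log2fc = np.log2((both.mean(axis=1) + eps) / (ctrl.mean(axis=1) + eps))
        padj = multipletests(p, method="fdr_bh")[1]
        rows.append(pd.DataFrame({"gene_id": ctrl.index, "dose": dose,
                                  "log2fc": log2fc.to_numpy(), "padj": padj}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# genome layout

def generate_genome_layout(cfg: SynthConfig,
                           rng: np.random.Generator | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(gene annotation, peak coordinates) on a toy chromosome.

    Peaks are placed one per equal-width slot (uniform within the slot)
    so true peaks never overlap; TSSs are uniform over the chromosome.
    Window membership downstream is therefore known by brute force.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    max_w = cfg.peak_width_range[1]
    slot = cfg.genome_length // cfg.n_peaks
    if slot < max_w + 2:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for {cfg.n_peaks} "
            f"peaks of width up to {max_w}")
    widths = rng.integers(cfg.peak_width_range[0], max_w + 1, size=cfg.n_peaks)
    offsets = rng.integers(0, slot - max_w - 1, size=cfg.n_peaks)
    starts = np.arange(cfg.n_peaks) * slot + offsets
    peaks = pd.DataFrame({
        "peak_id": [f"peak{i:05d}" for i in range(cfg.n_peaks)],
        "chrom": cfg.chrom, "start": starts, "end": starts + widths})

    tss = np.sort(rng.integers(0, cfg.genome_length, size=cfg.n_genes))
    genes = pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(cfg.n_genes)],
        "chrom": cfg.chrom, "tss": tss,
        "strand": rng.choice(["+", "-"], size=cfg.n_genes)})
    return genes, peaks


# ---------------------------------------------------------------------------
# peaks

def generate_peak_dataset(cfg: SynthConfig,
                          rng: np.random.Generator | None = None,
                          peak_coords: pd.DataFrame | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame,
                                     dict[int, pd.DataFrame], pd.DataFrame]:
    """(peak count table, sample annotations, summit sets, ground truth).

    The count table is wide (peak metadata plus one raw-count column per
    sample); raw counts are the true normalized counts scaled by a
    per-sample depth factor, which the normalization step must undo.
    Summit files carry one jittered summit per true peak per replicate,
    with ``summit_dropout`` exercising the majority rule.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if peak_coords is None:
        _, peak_coords = generate_genome_layout(cfg, rng)
    n = len(peak_coords)
    x0 = _loguniform(rng, *cfg.peak_baseline_range, n)
    ratio_a = _loguniform(rng, *cfg.delta_ratio_range, n)
    ratio_b = _loguniform(rng, *cfg.delta_ratio_range, n)
    responsive = rng.random(n) < cfg.frac_responsive_peaks
    ratio_a = np.where(responsive, ratio_a, 0.0)
    ratio_b = np.where(responsive, ratio_b, 0.0)
    mult = np.asarray(cfg.dose_multipliers)
    dA = x0[:, None] * ratio_a[:, None] * mult[None, :]
    dB = x0[:, None] * ratio_b[:, None] * mult[None, :]
    d_true = rng.normal(0.0, cfg.d_sd, size=n) if cfg.d_sd > 0 else np.zeros(n)
    d_true = np.where(responsive, d_true, 0.0)

    pred_add = x0[:, None] + dA + dB
    interaction = pred_add * d_true[:, None] - 0.0  # (x0+dA+dB)*(1+d) - (x0+dA+dB)
    cv = {sig: rng.uniform(*cfg.cv_range, size=n) for sig in CONDITION_SIGNALS}

    annotations = make_annotations(cfg.n_replicates,
                                   extra_controls=cfg.extra_controls,
                                   prefix="atac")
    means = _condition_means(x0, dA, dB, interaction)
    peak_ids = pd.Index(peak_coords["peak_id"])
    long = _draw_long(rng, annotations, means, cv, peak_ids, "norm_count")

    depth = pd.Series(
        rng.uniform(*cfg.depth_factor_range, size=len(annotations)),
        index=annotations["sample_id"])
    long["raw_count"] = long["norm_count"] * depth.loc[long["sample_id"]].to_numpy()
    counts = long.pivot(index="feature_id", columns="sample_id",
                        values="raw_count").reindex(peak_ids)
    counts = peak_coords.set_index("peak_id").join(counts).reset_index()

    mids = ((peak_coords["start"] + peak_coords["end"]) // 2).to_numpy()
    summits: dict[int, pd.DataFrame] = {}
    for rep in range(1, cfg.n_replicates + 1):
        keep = rng.random(n) >= cfg.summit_dropout
        jitter = np.rint(rng.normal(0.0, cfg.summit_jitter_sd, size=n)).astype(int)
        pos = np.clip(mids + jitter, 0, None)[keep]
        summits[rep] = pd.DataFrame(
            {"chrom": cfg.chrom, "pos": np.sort(pos)})

    truth = pd.DataFrame({
        "peak_id": peak_ids, "truth_x0": x0, "truth_d": d_true,
        "truth_responsive": responsive})
    for j, dose in enumerate(TREATMENT_DOSES):
        truth[f"truth_dA_{dose}"] = dA[:, j]
        truth[f"truth_dB_{dose}"] = dB[:, j]
    for sig in CONDITION_SIGNALS:
        truth[f"truth_cv_{sig}"] = cv[sig]
    return counts, annotations, summits, truth


# ---------------------------------------------------------------------------
# motifs

def generate_motif_matrix(peaks: pd.DataFrame, cfg: SynthConfig,
                          motif_names: list[str],
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Per-peak motif-match counts.

    With ``motif_clustering == 0`` each (peak, motif) count is Poisson
    with a shared rate (``motif_mean_matches`` expected matches per peak
    in total).  A positive clustering parameter gamma multiplies the rate
    by a per-(peak, motif) Gamma(1/gamma, gamma) factor, concentrating a
    motif's matches in few peaks (binding sites cluster in real data)
    while keeping the expected totals unchanged.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if not motif_names:
        raise ValueError("motif_names must be non-empty")
    n_peaks, n_motifs = len(peaks), len(motif_names)
    lam = np.full((n_peaks, n_motifs), cfg.motif_mean_matches / n_motifs)
    if cfg.motif_clustering > 0:
        g = cfg.motif_clustering
        lam = lam * rng.gamma(1.0 / g, g, size=lam.shape)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=pd.Index(peaks["peak_id"], name="peak_id"),
                        columns=motif_names)


# ---------------------------------------------------------------------------
# full bundle

def generate_dataset(cfg: SynthConfig, motif_names: list[str] | None = None
                     ) -> tuple[Dataset, pd.DataFrame, pd.DataFrame]:
    """Generate a complete, mutually consistent input bundle.

    Returns (dataset, gene ground truth, peak ground truth).
    """
    if motif_names is None:
        from .integrate import load_motif_groups
        motif_names = list(load_motif_groups()["motif"])
    rng = np.random.default_rng(cfg.seed)
    expression, expr_annot, gene_truth = generate_expression_dataset(cfg, rng)
    genes, peak_coords = generate_genome_layout(cfg, rng)
    genes = genes[genes["gene_id"].isin(gene_truth["gene_id"])]
    counts, peak_annot, summits, peak_truth = generate_peak_dataset(
        cfg, rng, peak_coords)
    de_table = generate_de_table(expression, expr_annot)
    motif_matrix = generate_motif_matrix(peak_coords, cfg, motif_names, rng)
    ds = Dataset(
        expression=expression, expression_annotations=expr_annot,
        peak_counts=counts, peak_annotations=peak_annot, summits=summits,
        de_table=de_table, genes=genes, motif_matrix=motif_matrix)
    return ds, gene_truth, peak_truth


def write_dataset(ds: Dataset, gene_truth: pd.DataFrame,
                  peak_truth: pd.DataFrame, out_dir) -> dict[str, object]:
    """Write the bundle in the exact formats the loaders read.

    Returns the ``paths`` mapping accepted by :func:`combisig.io.load_dataset`.
    """
    from pathlib import Path
    from .io import write_summits
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    for name, frame in (("expression", ds.expression),
                        ("expression_annotations", ds.expression_annotations),
                        ("peak_counts", ds.peak_counts),
                        ("peak_annotations", ds.peak_annotations),
                        ("de_table", ds.de_table),
                        ("genes", ds.genes)):
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p
    p = out / "motif_matrix.tsv"
    ds.motif_matrix.reset_index().to_csv(p, sep="\t", index=False)
    paths["motif_matrix"] = p
    summit_paths = []
    for rep, df in sorted(ds.summits.items()):
        sp = out / f"summits_rep{rep}.bed"
        write_summits(df, sp)
        summit_paths.append(sp)
    paths["summits"] = summit_paths
    gene_truth.to_csv(out / "gene_truth.tsv", sep="\t", index=False)
    peak_truth.to_csv(out / "peak_truth.tsv", sep="\t", index=False)
    return paths
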