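"""End-to-end orchestration of the analysis stages.

Stage order: noise model -> response estimates and classification ->
c/d values with master-set and reliability filters -> null simulations
and histogram analysis -> differential peak calling -> peak-gene and
motif integration.  Each stage logs its boundary and the seed it was
given; outputs are plain TSV tables plus a manifest, and a run is a pure
function of (inputs, config, seed).
"""
from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import integrate, io, noise, nulls, peaks, response
from .config import PipelineConfig, TREATMENT_DOSES

log = logging.getLogger("combisig")

STAGES = ("noise", "classify", "nulls", "callpeaks", "integrate")


def _stage(name: str, seed: int | None = None):
    log.info("=== stage %s%s ===", name,
             f" (seed {seed})" if seed is not None else "")
    return time.time()


def _expr_values(ds: io.Dataset) -> pd.DataFrame:
    return ds.expression.rename(columns={"gene_id": "feature_id",
                                         "tpm": "value"})


def _peak_values(norm: pd.DataFrame) -> pd.DataFrame:
    long = norm.reset_index().melt(id_vars="peak_id", var_name="sample_id",
                                   value_name="value")
    return long.rename(columns={"peak_id": "feature_id"})


def run_pipeline(ds: io.Dataset, config: PipelineConfig, out_dir: str | Path,
                 seed: int = 0, stages: tuple[str, ...] = STAGES,
                 integration_dose: str = "medium") -> dict[str, pd.DataFrame]:
    """Run the selected stages and write their tables under ``out_dir``.

    Returns the dict of result tables (also written as TSV + manifest).
    Stage dependencies are resolved automatically: requesting a late
    stage runs the earlier ones it needs, but only requested stages are
    written.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(STAGES, ss.spawn(len(STAGES)))}
    tables: dict[str, pd.DataFrame] = {}
    want = set(stages)
    unknown = want - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    # ---------------- noise model (always needed) ----------------
    _stage("noise", stage_seeds["noise"])
    gene_means, gene_cvs = noise.fit_noise_model(_expr_values(ds),
                                                 ds.expression_annotations)
    raw = ds.peak_counts.set_index("peak_id").drop(columns=["chrom", "start", "end"])
    norm = peaks.normalize_counts(raw)
    peak_means, peak_cvs = noise.fit_noise_model(_peak_values(norm),
                                                 ds.peak_annotations)
    if "noise" in want:
        tables["gene_cv"] = gene_cvs
        tables["peak_cv"] = peak_cvs
        tables["gene_condition_means"] = gene_means
        tables["peak_condition_means"] = peak_means

    # ---------------- responses + classification ----------------
    _stage("classify")
    gene_resp = noise.build_response_table(gene_means, gene_cvs, config.ci_level)
    gene_resp["category"] = noise.classify_gene_table(gene_resp)
    peak_resp = noise.build_response_table(peak_means, peak_cvs, config.ci_level)
    peak_resp["category"] = noise.classify_peak_table(peak_resp)
    peak_resp["upregulated_both"] = (peak_resp["dA"] > 0) & (peak_resp["dB"] > 0)

    master = response.select_master_set(
        ds.de_table, gene_resp, config.master_log2fc, config.master_padj)
    master_ids = set(master.loc[master["included"], "gene_id"])
    c_table = response.c_value_table(
        gene_resp[gene_resp["feature_id"].isin(master_ids)],
        config.reliability_min_tpm)
    d_table = response.d_value_table(peak_resp)
    trajectory, trajectory_partial = response.dose_trajectory(c_table)
    if "classify" in want:
        tables["gene_classification"] = gene_resp
        tables["peak_classification"] = peak_resp
        tables["master_set"] = master
        tables["c_values"] = c_table
        tables["d_values"] = d_table
        tables["c_trajectories"] = trajectory
        tables["c_trajectories_partial"] = trajectory_partial

    # ---------------- null simulations ----------------
    if "nulls" in want:
        _stage("nulls", stage_seeds["nulls"])
        rng = np.random.default_rng(stage_seeds["nulls"])
        master_resp = gene_resp[gene_resp["feature_id"].isin(master_ids)
                                & gene_resp["valid"]]
        p_mult = nulls.mixture_probabilities(
            master_resp[["dose", "category"]].dropna())
        sim_add = nulls.simulate_null(master_resp, gene_cvs, "additive",
                                      config.n_sims_gene, statistic="c", rng=rng)
        sim_mult = nulls.simulate_null(master_resp, gene_cvs, "multiplicative",
                                       config.n_sims_gene, statistic="c", rng=rng)
        sim_mix = nulls.simulate_null(master_resp, gene_cvs, "mixture",
                                      config.n_sims_gene, statistic="c",
                                      mixture_p_mult=p_mult, rng=rng)
        hist_rows, resid_rows, pois_rows = [], [], []
        for dose in TREATMENT_DOSES:
            obs = c_table.loc[(c_table["dose"] == dose)
                              & np.isfinite(c_table["c"]), "c"].to_numpy()
            if obs.size == 0:
                continue
            edges, obs_h = nulls.base_histogram(obs, config.hist_bin_width)
            per_sim = {}
            for sim in (sim_add, sim_mult, sim_mix):
                v = sim.values
                vals = v.loc[(v["dose"] == dose) & np.isfinite(v["value"]),
                             "value"].to_numpy()
                # per-feature simulations pooled; scaled to one draw per feature
                _, h = nulls.base_histogram(vals, config.hist_bin_width)
                per_sim[sim.mode] = h / max(sim.n_sims, 1)
            hist_rows.append(pd.DataFrame({
                "dose": dose, "bin_lo": edges, "observed": obs_h,
                "additive": per_sim["additive"],
                "multiplicative": per_sim["multiplicative"],
                "mixture": per_sim["mixture"]}))
            scale = nulls.fit_mixture_scale(obs_h, per_sim["mixture"], edges,
                                            config.hist_bin_width)
            p_add = 1.0 - p_mult.get(dose, 0.5)
            fit = nulls.residual_secondary_peak(
                obs_h, per_sim["additive"] * p_add, scale, edges,
                config.hist_bin_width, config.residual_fit_range)
            resid_rows.append((dose, scale, fit.center, fit.width,
                               fit.amplitude, fit.converged, fit.degenerate))
            pois = nulls.poisson_bin_pvalues(
                obs, master_resp[master_resp["dose"] == dose], gene_cvs,
                config.poisson_n_reps, config.hist_bin_width, config.hist_step,
                exclusion=config.poisson_exclusion, rng=rng)
            pois.insert(0, "dose", dose)
            pois_rows.append(pois)
        tables["c_histograms"] = pd.concat(hist_rows, ignore_index=True)
        tables["residual_fits"] = pd.DataFrame(
            resid_rows, columns=["dose", "mixture_scale", "center", "width",
                                 "amplitude", "converged", "degenerate"])
        tables["poisson_bin_pvalues"] = pd.concat(pois_rows, ignore_index=True)
        tables["mixture_probabilities"] = pd.DataFrame(
            sorted(p_mult.items()), columns=["dose", "p_multiplicative"])

    # ---------------- peak caller ----------------
    if "callpeaks" in want:
        _stage("callpeaks", stage_seeds["callpeaks"])
        consensus = peaks.consensus_peaks(ds.summits, config.consensus_width,
                                          config.consensus_min_support)
        master_consensus = peaks.build_master_consensus([consensus])
        grid = peaks.fdr_grid(norm, ds.peak_annotations, config.fc_grid,
                              config.count_grid)
        round1 = peaks.call_differential_peaks(grid, config.fdr_cell_threshold)
        peak_coords = ds.peak_counts[["peak_id", "chrom", "start", "end"]]
        merged, round2 = peaks.merge_and_recall(
            round1, peak_coords, norm, ds.peak_annotations,
            config.merge_distance_bp, config.second_round_min_fc,
            config.second_round_min_count)
        tables["consensus_peaks"] = consensus
        tables["master_consensus"] = master_consensus
        tables["differential_calls_round1"] = round1.calls
        tables["differential_calls_round2"] = round2.calls
        tables["merged_peaks"] = merged.assign(
            members=merged["members"].map(",".join) if len(merged) else None)
        tables["fdr_summary"] = pd.DataFrame({
            "round": [1, 2],
            "pooled_fdr": [round1.pooled_fdr, round2.pooled_fdr],
            "fp_estimate": [round1.n_false_positive_estimate,
                            round2.n_false_positive_estimate],
            "n_calls": [len(round1.calls), len(round2.calls)]})

    # ---------------- integration ----------------
    if "integrate" in want:
        _stage("integrate", stage_seeds["integrate"])
        rng = np.random.default_rng(stage_seeds["integrate"])
        dose = integration_dose
        gene_cat = (gene_resp[(gene_resp["dose"] == dose)
                              & gene_resp["feature_id"].isin(master_ids)]
                    .dropna(subset=["category"])
                    .rename(columns={"feature_id": "gene_id"})
                    [["gene_id", "category"]])
        up = peak_resp[(peak_resp["dose"] == dose)
                       & peak_resp["upregulated_both"]
                       & peak_resp["valid"]].dropna(subset=["category"])
        peak_cat = up.rename(columns={"feature_id": "peak_id"})[
            ["peak_id", "category"]]
        links = integrate.link_peaks_to_genes(ds.peak_counts, ds.genes,
                                              config.window_bp)
        groups = integrate.load_motif_groups()
        peak_meta = ds.peak_counts[["peak_id", "chrom", "start", "end"]].merge(
            peak_cat, on="peak_id", how="inner")
        labels = integrate.label_exclusive_peaks(
            peak_resp[peak_resp["dose"] == dose], config.dominance_threshold)
        d_dose = (d_table[d_table["dose"] == dose]
                  .rename(columns={"feature_id": "peak_id"}))
        d_up = d_dose[d_dose["peak_id"].isin(peak_cat["peak_id"])]

        tables["peak_gene_links"] = links
        tables["peak_counts_by_gene_category"] = \
            integrate.peak_class_counts_by_gene_category(
                links, peak_cat, gene_cat, config.n_bootstrap_genes,
                config.bootstrap_ci_level, rng)
        tables["exclusivity_labels"] = labels
        tables["dual_dominant_fraction"] = integrate.dual_dominant_gene_fraction(
            links, labels, gene_cat, config.n_bootstrap_genes,
            config.bootstrap_ci_level, rng)
        tables["motif_density"] = integrate.motif_density(
            peak_meta, ds.motif_matrix, groups, config.n_bootstrap_peaks,
            config.bootstrap_ci_level, rng)
        shuffle = integrate.dual_motif_shuffle_null(
            peak_meta, ds.motif_matrix, groups, config.n_shuffles, rng=rng)
        tables["dual_motif_null"] = shuffle.per_class
        scores = {sig: integrate.motif_enrichment_score(
                      ds.motif_matrix, norm, ds.peak_annotations, sig)
                  for sig in ("signalA", "signalB", "both")}
        tables["motif_enrichment_scores"] = pd.DataFrame(scores).rename_axis(
            "motif").reset_index()
        md_rows = []
        for motif in ds.motif_matrix.columns:
            med, lo, hi = integrate.motif_conditional_d(
                ds.motif_matrix, d_up, motif, config.n_bootstrap_peaks,
                config.bootstrap_ci_level, rng)
            md_rows.append((motif, med, lo, hi))
        tables["motif_conditional_d"] = pd.DataFrame(
            md_rows, columns=["motif", "median_d", "ci_lo", "ci_hi"])

    manifest = io.write_results(tables, out_dir)
    log.info("pipeline complete: %d tables written to %s", len(manifest), out_dir)
    return tables
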