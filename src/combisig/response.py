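"""Combined response factor (c) and accessibility deviation (d).

For a feature with baseline x0 and individual-signal effects dA, dB, the
additive prediction of the combined treatment is ``x0 + dA + dB`` and the
multiplicative prediction is ``x0 * (1 + dA/x0) * (1 + dB/x0)``; the two
differ by the interaction scale ``dA*dB/x0``.  The combined response
factor places the observed combined mean xAB linearly on that spectrum:

    c = (xAB - x0 - dA - dB) * x0 / (dA * dB)

so c = 0 is perfect addition and c = 1 perfect multiplication; c < 0 is
sub-additive and c > 1 super-multiplicative (for upregulated features).

For accessibility peaks, where addition is the default operation, the
deviation statistic is the fold-change difference from the additive
prediction, ``d = xAB / pred_add - 1``.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import TREATMENT_DOSES

EXCLUSION_REASONS = ("not_upregulated_combined", "negative_individual_delta",
                     "zero_baseline")


def compute_c(x0, dA, dB, xAB):
    """Combined response factor; NaN where x0 <= 0 or dA*dB == 0."""
    x0, dA, dB, xAB = (np.asarray(v, dtype=float) for v in (x0, dA, dB, xAB))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (xAB - x0 - dA - dB) * x0 / (dA * dB)
    c = np.where((x0 > 0) & (dA * dB != 0), c, np.nan)
    return c if c.ndim else float(c)


def compute_d(pred_add, xAB_observed):
    """Fold-change difference from the additive prediction; NaN if pred_add <= 0."""
    pred_add = np.asarray(pred_add, dtype=float)
    xAB = np.asarray(xAB_observed, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = xAB / pred_add - 1.0
    d = np.where(pred_add > 0, d, np.nan)
    return d if d.ndim else float(d)


def interaction_scale(x0, dA, dB):
    """dA*dB/x0 -- the gap between the multiplicative and additive predictions."""
    x0, dA, dB = (np.asarray(v, dtype=float) for v in (x0, dA, dB))
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dA * dB / x0
    s = np.where(x0 > 0, s, np.nan)
    return s if s.ndim else float(s)


def reliability_filter(x0, dA, dB, min_tpm: float = 2.0):
    """True where the c estimate is reliable (boundaries inclusive).

    Requires ``dA*dB/x0 >= min_tpm`` and ``dA*dB/x0 >= x0``: the c
    estimator's noise scales with 1/(dA*dB/x0), so small interaction
    scales make c dominated by technical variability.
    """
    scale = np.asarray(interaction_scale(x0, dA, dB))
    x0 = np.asarray(x0, dtype=float)
    ok = (scale >= min_tpm) & (scale >= x0)
    ok = np.where(np.isfinite(scale), ok, False).astype(bool)
    return ok if ok.ndim else bool(ok)


def c_value_table(responses: pd.DataFrame, min_tpm: float = 2.0) -> pd.DataFrame:
    """Per-(gene, dose) c values with interaction scale and reliability flag."""
    out = responses[["feature_id", "dose"]].copy()
    out["c"] = compute_c(responses["x0"], responses["dA"], responses["dB"],
                         responses["xAB"])
    out["interaction_scale"] = interaction_scale(responses["x0"],
                                                 responses["dA"], responses["dB"])
    out["reliable"] = reliability_filter(responses["x0"], responses["dA"],
                                         responses["dB"], min_tpm)
    out.loc[~responses["valid"].astype(bool), ["c", "interaction_scale"]] = np.nan
    out.loc[~responses["valid"].astype(bool), "reliable"] = False
    return out


def d_value_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-(peak, dose) d values against the additive prediction."""
    out = responses[["feature_id", "dose", "pred_add"]].copy()
    out["d"] = compute_d(responses["pred_add"], responses["xAB"])
    out.loc[~responses["valid"].astype(bool), "d"] = np.nan
    return out


def select_master_set(de_table: pd.DataFrame, responses: pd.DataFrame,
                      log2fc_threshold: float = 0.5,
                      padj_threshold: float = 0.05,
                      doses: Sequence[str] = TREATMENT_DOSES) -> pd.DataFrame:
    """Master set of upregulated genes.

    A gene is included iff it is significantly upregulated
    (log2FC >= ``log2fc_threshold`` and BH-adjusted p <= ``padj_threshold``)
    in ANY dose of the combined treatment, and its individual-signal
    effects satisfy dA > 0 and dB > 0 at ALL doses.  Genes with a zero
    control baseline are flagged for exclusion from c analyses (their c is
    identically undefined regardless of the signal effects).

    Parameters
    ----------
    de_table
        Columns ``gene_id, dose, log2fc, padj`` for the combined treatment.
    responses
        Response-estimate table (gene features).

    Returns
    -------
    DataFrame ``gene_id, included, reason`` where reason is one of
    ``not_upregulated_combined | negative_individual_delta | zero_baseline``
    or missing for included genes.
    """
    sig = de_table[(de_table["log2fc"] >= log2fc_threshold)
                   & (de_table["padj"] <= padj_threshold)]
    upregulated = set(sig["gene_id"])

    resp = responses[responses["dose"].isin(doses)]
    per_gene = resp.groupby("feature_id").agg(
        min_dA=("dA", "min"), min_dB=("dB", "min"),
        x0=("x0", "first"), n_doses=("dose", "nunique"))

    genes = sorted(set(de_table["gene_id"]) | set(per_gene.index))
    rows = []
    for gene in genes:
        if gene not in per_gene.index or per_gene.loc[gene, "n_doses"] < len(doses):
            rows.append((gene, False, "not_upregulated_combined"))
            continue
        g = per_gene.loc[gene]
        if gene not in upregulated:
            rows.append((gene, False, "not_upregulated_combined"))
        elif not (g["min_dA"] > 0 and g["min_dB"] > 0):
            rows.append((gene, False, "negative_individual_delta"))
        elif g["x0"] <= 0:
            rows.append((gene, False, "zero_baseline"))
        else:
            rows.append((gene, True, None))
    return pd.DataFrame(rows, columns=["gene_id", "included", "reason"])


def dose_trajectory(c_records: pd.DataFrame,
                    doses: Sequence[str] = TREATMENT_DOSES
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene c across doses, restricted to reliable estimates.

    Returns ``(full, partial)``: ``full`` has one row per gene reliable at
    every dose, with one ``c_<dose>`` column per dose ordered low to high;
    ``partial`` is the long table of reliable records for genes missing a
    reliable estimate at one or more doses.
    """
    reliable = c_records[c_records["reliable"].astype(bool)]
    counts = reliable.groupby("feature_id")["dose"].nunique()
    complete = set(counts[counts == len(doses)].index)
    wide = (reliable[reliable["feature_id"].isin(complete)]
            .pivot(index="feature_id", columns="dose", values="c"))
    full = wide.reindex(columns=list(doses))
    full.columns = [f"c_{d}" for d in doses]
    full = full.reset_index().rename(columns={"feature_id": "gene_id"})
    partial = reliable[~reliable["feature_id"].isin(complete)].reset_index(drop=True)
    return full, partial
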