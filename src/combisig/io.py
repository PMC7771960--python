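"""Readers and writers for the pipeline's file formats.

All tables are plain TSV; genomic intervals are BED-style, 0-based
half-open, with summits as single 0-based points.  Expression is a long
table (gene_id, sample_id, tpm) with sample metadata in a separate
annotation TSV.  A :class:`Dataset` bundles everything one run consumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import DOSES, SIGNALS

log = logging.getLogger("combisig")

EXPRESSION_COLUMNS = ["gene_id", "sample_id", "tpm"]
ANNOTATION_COLUMNS = ["sample_id", "signal", "dose", "replicate"]
GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]
DE_COLUMNS = ["gene_id", "dose", "log2fc", "padj"]


class FormatError(ValueError):
    """A file failed to parse under its declared format."""


@dataclass
class Dataset:
    """Everything one analysis run consumes, cross-reference checked."""

    expression: pd.DataFrame            # gene_id, sample_id, tpm
    expression_annotations: pd.DataFrame
    peak_counts: pd.DataFrame           # peak_id, chrom, start, end + sample cols
    peak_annotations: pd.DataFrame
    summits: dict[int, pd.DataFrame]    # replicate -> chrom, pos
    de_table: pd.DataFrame              # gene_id, dose, log2fc, padj
    genes: pd.DataFrame                 # gene_id, chrom, tss, strand
    motif_matrix: pd.DataFrame          # index peak_id, one column per motif
    excluded: dict[str, list] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers

def _read_tsv(path: Path, required: list[str], name: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{name} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {name} file {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name} file {path} lacks columns {missing}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(Path(path), EXPRESSION_COLUMNS, "expression")
    dup = df.duplicated(subset=["gene_id", "sample_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"duplicated (gene, sample) row in {path}: "
            f"gene_id={row['gene_id']!r} sample_id={row['sample_id']!r} "
            f"(line {int(df.index[dup][0]) + 2})")
    return df[EXPRESSION_COLUMNS]


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(Path(path), ANNOTATION_COLUMNS, "sample annotation")
    bad_signal = ~df["signal"].isin(SIGNALS)
    if bad_signal.any():
        raise FormatError(f"unknown signal value(s) in {path}: "
                          f"{sorted(df.loc[bad_signal, 'signal'].unique())}")
    bad_dose = ~df["dose"].isin(DOSES)
    if bad_dose.any():
        raise FormatError(f"unknown dose value(s) in {path}: "
                          f"{sorted(df.loc[bad_dose, 'dose'].unique())}")
    controlish = df["signal"].str.startswith("control")
    if (df.loc[controlish, "dose"] != "none").any():
        raise FormatError(f"control samples must have dose 'none' in {path}")
    dup = df.duplicated(subset=["signal", "dose", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"duplicated (signal, dose, replicate) triple in {path}: "
            f"{row['signal']}/{row['dose']}/rep{row['replicate']}")
    return df[ANNOTATION_COLUMNS]


def read_summits(path: str | Path) -> pd.DataFrame:
    """BED summit file -> DataFrame (chrom, pos), 0-based points."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"summit file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"summit BED {path} needs >= 3 columns")
    out = pd.DataFrame({"chrom": df[0].astype(str), "pos": df[1].astype(int)})
    if ((df[2].astype(int) - out["pos"]) != 1).any():
        raise FormatError(f"summit BED {path} must contain 1-bp intervals")
    return out


def read_peak_counts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(Path(path), ["peak_id", "chrom", "start", "end"], "peak counts")
    if df["peak_id"].duplicated().any():
        dup_id = df.loc[df["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise FormatError(f"duplicated peak_id in {path}: {dup_id!r}")
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].index[0]
        raise FormatError(f"peak with end <= start in {path} (line {bad + 2})")
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(Path(path), DE_COLUMNS, "differential expression")[DE_COLUMNS]


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(Path(path), GENE_COLUMNS, "gene annotation")
    if df["gene_id"].duplicated().any():
        dup_id = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"gene {dup_id!r} has more than one TSS in {path}")
    return df[GENE_COLUMNS]


def read_motif_matrix(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(Path(path), ["peak_id"], "motif matrix")
    return df.set_index("peak_id")


def load_dataset(paths: dict[str, str | Path]) -> Dataset:
    """Load and cross-check a full input bundle.

    ``paths`` keys: expression, expression_annotations, peak_counts,
    peak_annotations, summits (list of BED paths, replicate order),
    de_table, genes, motif_matrix.  Unresolvable cross-references are
    logged and recorded on ``Dataset.excluded`` rather than fatal.
    """
    ds = Dataset(
        expression=read_expression(paths["expression"]),
        expression_annotations=read_annotations(paths["expression_annotations"]),
        peak_counts=read_peak_counts(paths["peak_counts"]),
        peak_annotations=read_annotations(paths["peak_annotations"]),
        summits={i + 1: read_summits(p)
                 for i, p in enumerate(paths["summits"])},
        de_table=read_de_table(paths["de_table"]),
        genes=read_gene_annotation(paths["genes"]),
        motif_matrix=read_motif_matrix(paths["motif_matrix"]),
    )
    known_samples = set(ds.expression_annotations["sample_id"])
    orphan = sorted(set(ds.expression["sample_id"]) - known_samples)
    if orphan:
        raise FormatError(f"expression samples missing from annotations: {orphan}")

    known_peaks = set(ds.peak_counts["peak_id"])
    orphan_peaks = sorted(set(ds.motif_matrix.index) - known_peaks)
    if orphan_peaks:
        log.warning("motif matrix rows without a count-table peak: %d "
                    "(excluded)", len(orphan_peaks))
        ds.motif_matrix = ds.motif_matrix.drop(index=orphan_peaks)
        ds.excluded["motif_matrix_peaks"] = orphan_peaks

    known_genes = set(ds.genes["gene_id"])
    orphan_genes = sorted(set(ds.de_table["gene_id"]) - known_genes)
    if orphan_genes:
        log.warning("DE-table genes without a TSS annotation: %d (flagged)",
                    len(orphan_genes))
        ds.excluded["unannotated_de_genes"] = orphan_genes
    return ds


# ---------------------------------------------------------------------------
# writers

def write_summits(df: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame({"chrom": df["chrom"], "start": df["pos"],
                        "end": df["pos"] + 1})
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path
                  ) -> pd.DataFrame:
    """Write each table as ``<name>.tsv`` and return the manifest.

    Column order is preserved as given (deterministic); the manifest lists
    every file with its row count and is itself written as manifest.tsv.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    entries = []
    for name in sorted(tables):
        fname = f"{name}.tsv"
        frame = tables[name]
        frame.to_csv(out_dir / fname, sep="\t", index=False, float_format="%.10g")
        entries.append((fname, len(frame)))
    manifest = pd.DataFrame(entries, columns=["file", "n_rows"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
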