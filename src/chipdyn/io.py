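"""Readers and writers for the pipeline's tab-delimited interchange formats.

Formats:

* probe signal table — TSV with columns ``assay, factor, genotype, timepoint,
  probe_id, gene_id, offset, log2_ratio``; one row per probe measurement.
* promoter annotation table — TSV with ``gene_id, chrom, tss, strand``.
* peaks — BED6 plus two extra columns (``score_log2``, ``fdr``); the BED
  score column is ``1000·(1−fdr)`` clamped to [0, 1000].
* target sets — two-column TSV ``gene_id, sample``.
* expression matrices — TSV, rows = genes, columns = ``genotype:timepoint``
  sample labels.
* gene-set collections — GMT (set name, description, then gene ids).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .types import (
    FormatError,
    LookupGeneError,
    Peak,
    PromoterAnnotation,
    SampleKey,
    TargetSet,
    TILED_WINDOW,
    ValidationError,
    WINDOW_ORIGIN,
)

PROBE_COLUMNS = [
    "assay",
    "factor",
    "genotype",
    "timepoint",
    "probe_id",
    "gene_id",
    "offset",
    "log2_ratio",
]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_probe_table(path) -> dict[SampleKey, pd.DataFrame]:
    """Read a probe signal TSV, grouped by sample.

    Returns a dict mapping :class:`SampleKey` to a DataFrame with columns
    ``probe_id, gene_id, offset, log2_ratio`` sorted by (gene_id, offset).
    Offsets outside the tiled window or non-finite ratios raise
    :class:`ValidationError` citing the offending row.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, PROBE_COLUMNS, path)

    lo, hi = TILED_WINDOW
    bad = df.index[(df["offset"] < lo) | (df["offset"] >= hi)]
    if len(bad):
        row = int(bad[0]) + 2  # header is line 1
        raise ValidationError(
            f"{path}: offset {df.loc[bad[0], 'offset']} outside tiled window "
            f"[{lo}, {hi}) at line {row}"
        )
    nonfinite = df.index[~df["log2_ratio"].map(math.isfinite)]
    if len(nonfinite):
        raise ValidationError(
            f"{path}: non-finite log2_ratio at line {int(nonfinite[0]) + 2}"
        )

    groups: dict[SampleKey, pd.DataFrame] = {}
    for (assay, factor, genotype, timepoint), sub in df.groupby(
        ["assay", "factor", "genotype", "timepoint"], sort=True
    ):
        key = SampleKey(str(assay), str(factor), str(genotype), int(timepoint))
        groups[key] = (
            sub[["probe_id", "gene_id", "offset", "log2_ratio"]]
            .sort_values(["gene_id", "offset"], kind="mergesort")
            .reset_index(drop=True)
        )
    return groups


def write_probe_table(groups: Mapping[SampleKey, pd.DataFrame], path) -> None:
    """Write sample-grouped probe measurements back to a single TSV."""
    frames = []
    for key, sub in groups.items():
        out = sub[["probe_id", "gene_id", "offset", "log2_ratio"]].copy()
        out.insert(0, "timepoint", key.timepoint)
        out.insert(0, "genotype", key.genotype)
        out.insert(0, "factor", key.factor)
        out.insert(0, "assay", key.assay)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict[str, PromoterAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["gene_id", "chrom", "tss", "strand"], path)
    annotations: dict[str, PromoterAnnotation] = {}
    for row in df.itertuples(index=False):
        ann = PromoterAnnotation(str(row.gene_id), str(row.chrom), int(row.tss), str(row.strand))
        if ann.gene_id in annotations:
            raise ValidationError(f"{path}: duplicate gene_id {ann.gene_id!r}")
        annotations[ann.gene_id] = ann
    return annotations


def write_annotations(annotations: Mapping[str, PromoterAnnotation], path) -> None:
    pd.DataFrame(
        [(a.gene_id, a.chrom, a.tss, a.strand) for a in annotations.values()],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def window_to_genomic(
    start: int, end: int, annotation: PromoterAnnotation
) -> tuple[int, int]:
    """Convert a window-coordinate interval to a genomic BED interval.

    Window coordinate 0 sits at TSS offset −3250 (the upstream edge); for a
    + strand gene the interval maps to ``[tss + start − 3250, tss + end − 3250)``.
    For a − strand gene offsets run toward decreasing genomic coordinates, so
    the point set mirrors across the TSS: base at offset o sits at genomic
    ``tss − o``, giving ``[tss − (end − 3250) + 1, tss − (start − 3250) + 1)``.
    The conversion is an involution: applying it twice recovers the input.
    """
    s_off = start + WINDOW_ORIGIN  # TSS-relative offsets
    e_off = end + WINDOW_ORIGIN
    if annotation.strand == "+":
        return annotation.tss + s_off, annotation.tss + e_off
    return annotation.tss - e_off + 1, annotation.tss - s_off + 1


def genomic_to_window(
    gstart: int, gend: int, annotation: PromoterAnnotation
) -> tuple[int, int]:
    """Inverse of :func:`window_to_genomic`."""
    if annotation.strand == "+":
        s_off = gstart - annotation.tss
        e_off = gend - annotation.tss
    else:
        s_off = annotation.tss - gend + 1
        e_off = annotation.tss - gstart + 1
    return s_off - WINDOW_ORIGIN, e_off - WINDOW_ORIGIN


def write_peaks_bed(
    peaks: Iterable[Peak],
    annotations: Mapping[str, PromoterAnnotation],
    path,
) -> None:
    """Write peaks as BED6 + (score_log2, fdr) in genomic coordinates.

    BED score = ``1000·(1−fdr)`` rounded and clamped to [0, 1000]; peaks with
    no FDR estimate yet get score 0.
    """
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand\tscore_log2\tfdr"]
    for peak in peaks:
        ann = annotations.get(peak.gene_id)
        if ann is None:
            raise LookupGeneError(f"peak gene {peak.gene_id!r} not in annotations")
        gstart, gend = window_to_genomic(peak.start, peak.end, ann)
        fdr = peak.fdr
        bed_score = 0 if fdr != fdr else int(round(1000 * (1 - fdr)))
        bed_score = max(0, min(1000, bed_score))
        fdr_txt = "NA" if fdr != fdr else f"{fdr:.6g}"
        lines.append(
            f"{ann.chrom}\t{gstart}\t{gend}\t{peak.gene_id}\t{bed_score}\t"
            f"{ann.strand}\t{peak.score:.6g}\t{fdr_txt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaks_bed(path, annotations: Mapping[str, PromoterAnnotation]) -> list[Peak]:
    """Read peaks written by :func:`write_peaks_bed` back into window coordinates."""
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise FormatError(f"{path}:{lineno}: expected 8 BED columns, got {len(fields)}")
        _, gstart, gend, gene_id, _, _, score_log2, fdr_txt = fields
        ann = annotations.get(gene_id)
        if ann is None:
            raise LookupGeneError(f"{path}:{lineno}: unknown gene {gene_id!r}")
        start, end = genomic_to_window(int(gstart), int(gend), ann)
        fdr = float("nan") if fdr_txt == "NA" else float(fdr_txt)
        peaks.append(Peak(gene_id, start, end, float(score_log2), fdr))
    return peaks


def write_target_sets(sets: Iterable[TargetSet], path) -> None:
    rows = []
    for ts in sets:
        label = f"chip:{ts.factor}:{ts.genotype}:{ts.timepoint_label}"
        rows.extend((gene, label) for gene in sorted(ts.genes))
    pd.DataFrame(rows, columns=["gene_id", "sample"]).to_csv(path, sep="\t", index=False)


def read_target_sets(path) -> list[TargetSet]:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["gene_id", "sample"], path)
    sets = []
    for label, sub in df.groupby("sample", sort=True):
        parts = str(label).split(":")
        if len(parts) != 4:
            raise FormatError(f"{path}: bad sample label {label!r}")
        _, factor, genotype, timepoint = parts
        sets.append(TargetSet(factor, genotype, timepoint, frozenset(sub["gene_id"].astype(str))))
    return sets


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Write an expression matrix (rows genes, MultiIndex columns (genotype, timepoint))."""
    out = matrix.copy()
    out.columns = [f"{g}:{t}" for g, t in matrix.columns]
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    cols = []
    for col in df.columns:
        parts = col.split(":")
        if len(parts) != 2:
            raise FormatError(f"{path}: expression column {col!r} is not genotype:timepoint")
        cols.append((parts[0], int(parts[1])))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["genotype", "timepoint"])
    return df


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set collection: name, description, gene ids per line."""
    collection: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        collection[fields[0]] = frozenset(fields[2:])
    return collection


def write_gmt(collection: Mapping[str, Iterable[str]], path) -> None:
    lines = [
        "\t".join([name, name] + sorted(genes)) for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
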