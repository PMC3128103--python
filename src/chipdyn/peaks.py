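"""Peak calling for promoter tiling windows with permutation-based FDR.

The caller is deliberately simple and fully specified: per promoter window,
slide a fixed-width window across the probe offsets; a window is a
candidate when it holds at least ``min_probes`` probes whose mean
normalized log2 ratio reaches ``score_threshold``; overlapping candidate
windows merge into maximal runs, each emitting one peak spanning its member
probes.  Significance comes from an empirical null built by permuting probe
values *within* each promoter window and re-scanning, which preserves
per-promoter probe counts and local variance structure.  The peak FDR at
score s is the expected number of null peaks scoring >= s per permutation,
divided by the observed number of peaks scoring >= s, made monotone in s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ChipdynError, ConfigError, Peak, ValidationError, WINDOW_ORIGIN

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tukey biweight normalization


def biweight_location(
    values: Sequence[float], c: float = 9.0, tol: float = 1e-9, max_iter: int = 100
) -> float:
    """Tukey biweight location with tuning constant c and raw-MAD scale.

    Iteratively reweighted mean started at the median; observations more
    than ``c`` MADs out get zero weight.  When the MAD is zero (more than
    half the values identical) the median is returned instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("biweight_location of empty input")
    t = float(np.median(x))
    mad = float(np.median(np.abs(x - t)))
    if mad == 0.0:
        log.info("MAD is zero; falling back to median location")
        return t
    for _ in range(max_iter):
        u = (x - t) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        total = w.sum()
        if total == 0.0:
            break
        t_new = float(np.sum(w * x) / total)
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    return t


def normalize_biweight(probes: pd.DataFrame) -> pd.DataFrame:
    """Centre one sample's log2 ratios by subtracting their biweight mean.

    The location is estimated over the whole sample (all promoters), the
    array-level normalization applied between samples.
    """
    if len(probes) < 2:
        raise ValidationError("normalization needs at least 2 probes")
    location = biweight_location(probes["log2_ratio"].to_numpy())
    out = probes.copy()
    out["log2_ratio"] = out["log2_ratio"] - location
    return out


# ---------------------------------------------------------------------------
# Window scan


def _scan_sorted(
    offsets: np.ndarray,
    values: np.ndarray,
    window_bp: int,
    min_probes: int,
    score_threshold: float,
) -> list[tuple[int, int, float]]:
    """Scan one promoter's sorted probes; return merged (start_off, end_off, score).

    Every possible window placement is considered.  Distinct placements with
    the same first probe are nested, so per first-probe index i the scan
    looks for the largest last-probe index j whose probe set is realizable by
    some window start (truncated sets arise at the left edge of the tiled
    region and after inter-probe gaps) and whose mean passes the threshold.
    Coordinates returned are TSS-relative probe offsets, half-open
    ``[first member offset, last member offset + 1)``.
    """
    n = len(offsets)
    ends = np.searchsorted(offsets, offsets + window_bp, side="left")
    cs = np.concatenate(([0.0], np.cumsum(values)))
    cand: list[tuple[int, int]] = []  # (first index, stop index) per candidate
    for i in range(n):
        j = ends[i] - 1
        while j >= i + min_probes - 1:
            if j < ends[i] - 1:
                # a window whose last probe is j (not j_max) must start low
                # enough to exclude probe j+1 yet still begin after probe i-1
                if i > 0 and offsets[j + 1] - window_bp < offsets[i - 1] + 1:
                    break
            if (cs[j + 1] - cs[i]) / (j + 1 - i) >= score_threshold:
                cand.append((i, j + 1))
                break
            j -= 1
    if not cand:
        return []
    peaks = []
    run_start, run_stop = cand[0]
    prev = cand[0][0]
    for i, stop in cand[1:]:
        if offsets[i] < offsets[prev] + window_bp:  # overlap/touch -> merge
            prev = i
            run_stop = max(run_stop, stop)
        else:
            peaks.append(_emit(offsets, cs, run_start, run_stop))
            run_start, run_stop = i, stop
            prev = i
    peaks.append(_emit(offsets, cs, run_start, run_stop))
    return peaks


def _emit(offsets, cs, first: int, stop: int) -> tuple[int, int, float]:
    score = (cs[stop] - cs[first]) / (stop - first)
    return int(offsets[first]), int(offsets[stop - 1]) + 1, float(score)


def _infer_spacing(offsets: np.ndarray) -> int | None:
    diffs = np.diff(offsets)
    diffs = diffs[diffs > 0]
    return int(diffs.min()) if diffs.size else None


def _grouped(probes: pd.DataFrame):
    """Yield (gene_id, offsets, values) with offsets sorted ascending."""
    for gene, sub in probes.groupby("gene_id", sort=True):
        order = np.argsort(sub["offset"].to_numpy(), kind="mergesort")
        yield gene, sub["offset"].to_numpy()[order], sub["log2_ratio"].to_numpy()[order]


def _as_grid(probes: pd.DataFrame):
    """Return (genes, grid, value matrix) when every gene shares one offset grid."""
    counts = probes.groupby("gene_id", sort=True).size()
    if counts.empty or counts.nunique() != 1:
        return None
    p = int(counts.iloc[0])
    sub = probes.sort_values(["gene_id", "offset"], kind="mergesort")
    offsets = sub["offset"].to_numpy().reshape(-1, p)
    if not (offsets == offsets[0]).all():
        return None
    genes = counts.index.to_numpy()
    values = sub["log2_ratio"].to_numpy().reshape(-1, p)
    return genes, offsets[0].astype(int), values


def _grid_scan(
    grid: np.ndarray,
    values: np.ndarray,
    window_bp: int,
    min_probes: int,
    score_threshold: float,
    scores_only: bool = False,
):
    """Vectorized scan of many promoters sharing one probe grid.

    Returns either a flat array of merged-peak scores (``scores_only``) or a
    list of per-row lists of (start_off, end_off, score).
    """
    g, p = values.shape
    ends = np.searchsorted(grid, grid + window_bp, side="left")
    counts = ends - np.arange(p)
    valid = counts >= min_probes
    cs = np.concatenate([np.zeros((g, 1)), np.cumsum(values, axis=1)], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (cs[:, ends] - cs[:, np.arange(p)]) / counts
    cand = valid[None, :] & (means >= score_threshold)
    # Left-edge truncated windows: a window starting below the grid can hold
    # only the first L probes (min_probes <= L < ends[0]); the candidate for
    # first-probe 0 is its largest passing probe set.
    k0 = int(ends[0])
    stop0 = np.where(cand[:, 0], k0, 0)
    for trunc in range(k0 - 1, min_probes - 1, -1):
        newly = (stop0 == 0) & ((cs[:, trunc] / trunc) >= score_threshold)
        stop0[newly] = trunc
    cand[:, 0] = stop0 > 0
    rows = np.flatnonzero(cand.any(axis=1))

    if scores_only:
        out_scores: list[float] = []
    else:
        out: list[list[tuple[int, int, float]]] = [[] for _ in range(g)]
    for r in rows:
        idx = np.flatnonzero(cand[r])
        csr = cs[r]

        def stop_of(col: int) -> int:
            return int(stop0[r]) if col == 0 else int(ends[col])

        run_start, run_stop = idx[0], stop_of(idx[0])
        prev = idx[0]
        for i in idx[1:]:
            if grid[i] < grid[prev] + window_bp:
                prev = i
                run_stop = max(run_stop, stop_of(i))
            else:
                item = _emit(grid, csr, run_start, run_stop)
                (out_scores.append(item[2]) if scores_only else out[r].append(item))
                run_start, run_stop = i, stop_of(i)
                prev = i
        item = _emit(grid, csr, run_start, run_stop)
        (out_scores.append(item[2]) if scores_only else out[r].append(item))
    return np.asarray(out_scores) if scores_only else out


def call_peaks(
    probes: pd.DataFrame,
    window_bp: int = 500,
    min_probes: int = 4,
    score_threshold: float = 0.5,
) -> list[Peak]:
    """Call enriched intervals in every promoter window of one sample.

    ``probes`` must carry ``gene_id, offset, log2_ratio`` (already
    normalized).  Peak coordinates are window coordinates (0 = upstream edge
    of the tiled window); ``fdr`` is left NaN for :func:`estimate_fdr`.
    """
    if probes.empty:
        return []
    spacing = _infer_spacing(np.sort(probes["offset"].to_numpy()))
    if spacing is not None and window_bp < spacing:
        raise ConfigError(
            f"window_bp={window_bp} is smaller than the probe spacing ({spacing})"
        )
    peaks: list[Peak] = []
    gridded = _as_grid(probes)
    if gridded is not None:
        genes, grid, values = gridded
        per_row = _grid_scan(grid, values, window_bp, min_probes, score_threshold)
        for gene, items in zip(genes, per_row):
            for s, e, score in items:
                peaks.append(Peak(gene, s - WINDOW_ORIGIN, e - WINDOW_ORIGIN, score))
    else:
        for gene, offsets, values in _grouped(probes):
            for s, e, score in _scan_sorted(
                offsets, values, window_bp, min_probes, score_threshold
            ):
                peaks.append(Peak(gene, s - WINDOW_ORIGIN, e - WINDOW_ORIGIN, score))
    return peaks


# ---------------------------------------------------------------------------
# Permutation FDR


def estimate_fdr(
    peaks: Sequence[Peak],
    probes: pd.DataFrame,
    n_permutations: int = 25,
    seed: int = 0,
    window_bp: int = 500,
    min_probes: int = 4,
    score_threshold: float = 0.5,
) -> list[Peak]:
    """Attach permutation FDRs to peaks called from ``probes``.

    The null re-scores every promoter window after shuffling its probe
    values in place, ``n_permutations`` times.  For an observed peak with
    score s, the raw FDR is ``min(1, E_null[#peaks >= s] / #observed >= s)``;
    a final cumulative-minimum pass in ascending score order makes the
    estimate monotone non-increasing in score (a q-value), so ties share one
    value and a score beating every null is reported as 0 — i.e. below the
    1/n_permutations resolution of the null.
    """
    if n_permutations < 1:
        raise ChipdynError("n_permutations must be >= 1")
    if not peaks:
        return []
    rng = np.random.default_rng(seed)

    null_scores: list[np.ndarray] = []
    gridded = _as_grid(probes)
    if gridded is not None:
        _, grid, values = gridded
        for _ in range(n_permutations):
            perm = rng.permuted(values, axis=1)
            null_scores.append(
                _grid_scan(grid, perm, window_bp, min_probes, score_threshold, scores_only=True)
            )
    else:
        groups = list(_grouped(probes))
        for _ in range(n_permutations):
            batch = []
            for _, offsets, values in groups:
                batch.extend(
                    s for _, _, s in _scan_sorted(
                        offsets, rng.permutation(values), window_bp, min_probes, score_threshold
                    )
                )
            null_scores.append(np.asarray(batch))
    null = np.sort(np.concatenate(null_scores)) if null_scores else np.array([])

    obs = np.array([p.score for p in peaks])
    order = np.argsort(obs, kind="mergesort")  # ascending score
    sorted_scores = obs[order]
    # observed peaks with score >= s, for s at each sorted position
    n_obs_ge = len(obs) - np.searchsorted(sorted_scores, sorted_scores, side="left")
    n_null_ge = len(null) - np.searchsorted(null, sorted_scores, side="left")
    raw = np.minimum(1.0, (n_null_ge / n_permutations) / n_obs_ge)
    # q-value convention: fdr at score s = min raw FDR over thresholds <= s,
    # which is monotone non-increasing in score.
    fdr_sorted = np.minimum.accumulate(raw)
    result: list[Peak] = [None] * len(peaks)  # type: ignore[list-item]
    for pos, peak_idx in enumerate(order):
        p = peaks[peak_idx]
        result[peak_idx] = Peak(p.gene_id, p.start, p.end, p.score, float(fdr_sorted[pos]))
    return result


# ---------------------------------------------------------------------------
# FDR-threshold calibration against known targets


@dataclass(frozen=True)
class CalibrationReport:
    """Recovery of a known-target list across candidate FDR thresholds."""

    table: pd.DataFrame  # threshold, n_targets, n_known_recovered, n_known_total
    chosen_threshold: float


def calibrate_fdr_threshold(
    peak_sets: Mapping[float, Iterable[str]],
    known_targets: Iterable[str],
    recovery_goal: float = 1.0,
) -> CalibrationReport:
    """Pick the smallest FDR threshold recovering the known targets.

    ``peak_sets`` maps candidate thresholds to the gene-level target sets
    they produce.  The chosen threshold is the smallest whose recovery of
    ``known_targets`` reaches ``recovery_goal``; if none qualifies, the
    threshold with maximal recovery (smallest on ties) is returned.
    """
    known = set(known_targets)
    if not known:
        raise ChipdynError("calibration undefined for an empty known-target list")
    rows = []
    for threshold in sorted(peak_sets):
        genes = set(
            peak_sets[threshold].genes
            if hasattr(peak_sets[threshold], "genes")
            else peak_sets[threshold]
        )
        rows.append(
            {
                "threshold": threshold,
                "n_targets": len(genes),
                "n_known_recovered": len(known & genes),
                "n_known_total": len(known),
            }
        )
    table = pd.DataFrame(rows)
    recovery = table["n_known_recovered"] / table["n_known_total"]
    hits = table.index[recovery >= recovery_goal]
    if len(hits):
        chosen = float(table.loc[hits[0], "threshold"])
    else:
        chosen = float(table.loc[recovery.idxmax(), "threshold"])
        log.warning(
            "no threshold reached recovery goal %.3g; best recovery %.3g at %.3g",
            recovery_goal,
            recovery.max(),
            chosen,
        )
    return CalibrationReport(table, chosen)
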