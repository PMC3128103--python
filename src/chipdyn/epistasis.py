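"""Expression filtering, normalization, clustering, and rule-based epistasis
classification of genotype × time profiles.

Expression matrices are pandas DataFrames with genes as rows and a
(genotype, timepoint) MultiIndex over columns; genotypes are WT, Sirt6KO
and the Sirt6/RelA double knockout (DKO), timepoints minutes after TNF-α.
Classification compares, per timepoint, the Sirt6KO/WT and DKO/WT fold
ratios against explicit thresholds; the classes encode whether loss of
Sirt6 derepresses a gene (at all times / only under TNF / only at baseline)
and whether additional loss of RelA reverts the change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .types import ChipdynError, EpistasisCall, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpistasisRuleParams:
    """Fold thresholds for "elevated"/"repressed" and DKO reversion.

    The source heatmaps state directions, not cutoffs; 1.5× is the
    conventional array fold threshold and is exposed here explicitly.
    A DKO value counts as reverted when DKO/WT stays below ``up_fold``.
    """

    up_fold: float = 1.5
    down_fold: float = 1.0 / 1.5

    def __post_init__(self) -> None:
        if not self.up_fold > 1.0 > self.down_fold > 0.0:
            raise ValidationError("need up_fold > 1 > down_fold > 0")


def filter_expressed(
    detections: pd.DataFrame, detection_floor: float = 100.0
) -> pd.DataFrame:
    """Keep genes whose maximum detection over all samples reaches the floor
    (inclusive)."""
    keep = detections.max(axis=1) >= detection_floor
    return detections.loc[keep]


def normalize_to_reference(detections: pd.DataFrame) -> pd.DataFrame:
    """Fold changes relative to the untreated wild-type sample (WT, t=0).

    Genes whose reference detection is <= 0 are dropped (with a logged
    count); the reference cell becomes exactly 1 for every retained gene.
    """
    if ("WT", 0) not in detections.columns:
        raise ChipdynError("normalization requires a (WT, 0) reference column")
    ref = detections[("WT", 0)]
    bad = ref <= 0
    if bad.any():
        log.warning("dropping %d gene(s) with non-positive (WT, 0) reference", int(bad.sum()))
    kept = detections.loc[~bad]
    return kept.div(kept[("WT", 0)], axis=0)


def classify_epistasis(
    fold: pd.Series, rules: EpistasisRuleParams = EpistasisRuleParams()
) -> EpistasisCall:
    """Classify one gene's fold-change profile into an epistasis class.

    ``fold`` is indexed by (genotype, timepoint) with genotypes WT, Sirt6KO,
    DKO sharing timepoints that include t=0 and at least one TNF timepoint.
    Per timepoint t let up(t): Sirt6KO/WT >= up_fold; down(t): Sirt6KO/WT <=
    down_fold; reverted(t): DKO/WT < up_fold; over(t): DKO/WT >= up_fold.

    AllUp — up at t=0 and at every TNF timepoint, reverted everywhere;
    TNFUp — up at >= 1 TNF timepoint but not at t=0, reverted wherever up;
    ZeroUp — up at t=0 only, reverted there; Inverse — down somewhere and
    over somewhere (Sirt6 loss represses, additional RelA loss overshoots);
    RelABlockedSirt6 — up somewhere without reversion there (RelA loss fails
    to revert because RelA was blocking Sirt6, not recruiting it);
    Unclassified otherwise.  Precedence: AllUp > TNFUp > ZeroUp > Inverse >
    RelABlockedSirt6 > Unclassified.
    """
    gene_id = fold.name if fold.name is not None else ""
    genotypes = fold.index.get_level_values(0)
    for geno in ("WT", "Sirt6KO", "DKO"):
        if geno not in genotypes:
            raise ChipdynError(f"profile missing genotype {geno!r}")
    timepoints = sorted(set(fold.index.get_level_values(1)))
    if 0 not in timepoints or len(timepoints) < 2:
        raise ChipdynError("profile needs t=0 and at least one TNF timepoint")
    tnf = [t for t in timepoints if t != 0]

    up, down, reverted, over = {}, {}, {}, {}
    for t in timepoints:
        wt = fold[("WT", t)]
        ko_ratio = fold[("Sirt6KO", t)] / wt
        dko_ratio = fold[("DKO", t)] / wt
        up[t] = ko_ratio >= rules.up_fold
        down[t] = ko_ratio <= rules.down_fold
        reverted[t] = dko_ratio < rules.up_fold
        over[t] = dko_ratio >= rules.up_fold

    if up[0] and all(up[t] for t in tnf) and reverted[0] and all(reverted[t] for t in tnf):
        label = "AllUp"
    elif (
        not up[0]
        and any(up[t] for t in tnf)
        and all(reverted[t] for t in tnf if up[t])
    ):
        label = "TNFUp"
    elif up[0] and not any(up[t] for t in tnf) and reverted[0]:
        label = "ZeroUp"
    elif any(down[t] for t in timepoints) and any(over[t] for t in timepoints):
        label = "Inverse"
    elif any(up[t] and not reverted[t] for t in timepoints):
        label = "RelABlockedSirt6"
    else:
        label = "Unclassified"
    return EpistasisCall(str(gene_id), label)


def classify_all(
    folds: pd.DataFrame, rules: EpistasisRuleParams = EpistasisRuleParams()
) -> pd.Series:
    """Epistasis label per gene (rows of a fold-change matrix)."""
    return pd.Series(
        {gene: classify_epistasis(row, rules).label for gene, row in folds.iterrows()},
        name="epistasis_class",
    )


def count_classes(calls) -> pd.Series:
    """Per-label counts plus the antagonistic total (AllUp + TNFUp + ZeroUp)."""
    labels = [c.label if isinstance(c, EpistasisCall) else str(c) for c in calls]
    counts = pd.Series(labels).value_counts().reindex(EpistasisCall.LABELS, fill_value=0)
    counts["antagonistic"] = sum(counts[l] for l in EpistasisCall.ANTAGONISTIC)
    return counts


def hierarchical_cluster(folds: pd.DataFrame):
    """Average-linkage clustering of genes under the 1 − Pearson distance.

    Returns ``(leaf_order, linkage_matrix)`` where ``leaf_order`` lists the
    gene ids in dendrogram order, with the deterministic convention that at
    each merge the subtree containing the smaller original row index comes
    first.  Rows with zero variance have undefined correlation; their
    distance to everything is defined as 1 (logged).
    """
    if len(folds) < 2:
        raise ChipdynError("clustering needs at least 2 genes")
    values = folds.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant row(s); correlation undefined, distance set to 1",
                    int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    dist = np.clip(dist, 0.0, None)
    merge = linkage(squareform(dist, checks=False), method="average")

    n = len(folds)
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    mins: dict[int, int] = {i: i for i in range(n)}
    for step, row in enumerate(merge):
        a, b = int(row[0]), int(row[1])
        first, second = (a, b) if mins[a] <= mins[b] else (b, a)
        node = n + step
        leaves[node] = leaves[first] + leaves[second]
        mins[node] = min(mins[a], mins[b])
    order = leaves[n + len(merge) - 1]
    return [folds.index[i] for i in order], merge
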