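"""Occupancy matrices, temporal dynamics, co-occupancy statistics and
RelA-dependence classification.

The central object is a genes × (factor, genotype, timepoint) binary
occupancy matrix assembled from control-subtracted target sets.  On top of
it sit: a rule-based classification of each gene's 4-timepoint occupancy
pattern; the hypergeometric co-occupancy test (log-space, so p-values far
below the float underflow limit remain representable); the between-factor
binding-site distance; and the abrogated/reduced/independent classification
of Sirt6 occupancy in RelA-null cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .types import ChipdynError, DependenceCall, Peak, TargetSet, ValidationError

DYNAMICS_LABELS = (
    "unbound",
    "constitutive",
    "periodic",
    "baseline_vacated",
    "induced",
    "other",
)


def build_occupancy_matrix(
    target_sets: Iterable[TargetSet], universe: Iterable[str]
) -> pd.DataFrame:
    """Genes × (factor, genotype, timepoint) 0/1 matrix over a fixed universe."""
    genes = pd.Index(universe, name="gene_id")
    columns = []
    data = {}
    for ts in target_sets:
        key = (ts.factor, ts.genotype, ts.timepoint_label)
        if key in data:
            raise ChipdynError(f"duplicate sample {key} in occupancy matrix")
        missing = ts.genes - set(genes)
        if missing:
            raise ChipdynError(f"target genes outside universe: {sorted(missing)[:3]}...")
        columns.append(key)
        data[key] = genes.isin(ts.genes).astype(np.int8)
    matrix = pd.DataFrame(data, index=genes)
    matrix.columns = pd.MultiIndex.from_tuples(columns, names=["factor", "genotype", "timepoint"])
    return matrix


def classify_dynamics(bits: Sequence[int]) -> str:
    """Label a 4-bit occupancy pattern over timepoints (0, 15, 30, 60) min.

    unbound (0,0,0,0); constitutive (1,1,1,1); periodic: on at 15, off at
    30, back on at 60 (any baseline state); baseline_vacated: bound only
    before TNF; induced: unbound at baseline, bound at >= 1 later timepoint;
    other: the rest.  Precedence: unbound > constitutive > periodic >
    baseline_vacated > induced > other.
    """
    if len(bits) != 4:
        raise ValidationError(f"expected 4 occupancy bits, got {len(bits)}")
    b0, b15, b30, b60 = (int(b) for b in bits)
    if not all(b in (0, 1) for b in (b0, b15, b30, b60)):
        raise ValidationError("occupancy bits must be 0/1")
    if (b0, b15, b30, b60) == (0, 0, 0, 0):
        return "unbound"
    if (b0, b15, b30, b60) == (1, 1, 1, 1):
        return "constitutive"
    if (b15, b30, b60) == (1, 0, 1):
        return "periodic"
    if b0 == 1 and (b15, b30, b60) == (0, 0, 0):
        return "baseline_vacated"
    if b0 == 0 and (b15 or b30 or b60):
        return "induced"
    return "other"


def dynamics_counts(occupancy: pd.DataFrame) -> pd.Series:
    """Tally dynamics labels over the rows of a genes × 4-timepoint matrix."""
    labels = [classify_dynamics(row) for row in occupancy.to_numpy()]
    return pd.Series(labels).value_counts().reindex(DYNAMICS_LABELS, fill_value=0)


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric overlap of two gene sets in a universe."""

    universe_n: int
    set_a_n: int
    set_b_n: int
    overlap_k: int
    log10_p: float

    @property
    def frac_of_a(self) -> float:
        return self.overlap_k / self.set_a_n

    @property
    def frac_of_b(self) -> float:
        return self.overlap_k / self.set_b_n


def overlap_hypergeometric(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapTest:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed in log space.

    ``set_a`` plays the role of the K marked genes, ``set_b`` of the n
    draws; k is the observed overlap.  Computed via the log survival
    function so p-values below 1e-300 stay representable.
    """
    uni = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= uni or not b <= uni:
        raise ChipdynError("overlap sets must be subsets of the universe")
    n_uni, k_a, k_b = len(uni), len(a), len(b)
    k = len(a & b)
    log10_p = float(hypergeom.logsf(k - 1, n_uni, k_a, k_b) / np.log(10.0))
    return OverlapTest(n_uni, k_a, k_b, k, min(log10_p, 0.0))


def overlap_fraction(overlap_k: int, set_n: int) -> float:
    """Overlap percentage with the reporting convention used for headline
    numbers: nearest integer at >= 20%, one decimal below 20%."""
    if set_n <= 0:
        raise ChipdynError("overlap_fraction needs a non-empty set")
    if overlap_k > set_n:
        raise ChipdynError("overlap cannot exceed set size")
    pct = 100.0 * overlap_k / set_n
    return float(round(pct)) if pct >= 20 else round(pct, 1)


def site_distance(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> int:
    """Minimum centre-to-centre distance (bp) between two factors' peaks at
    one gene; centres are floor((start+end)/2)."""
    if not peaks_a or not peaks_b:
        raise ChipdynError("site_distance needs >= 1 peak per factor")
    return min(abs(pa.center - pb.center) for pa in peaks_a for pb in peaks_b)


def fraction_within(
    shared_genes: Iterable[str],
    peaks_by_gene_a: Mapping[str, Sequence[Peak]],
    peaks_by_gene_b: Mapping[str, Sequence[Peak]],
    threshold_bp: int = 500,
) -> tuple[float, int]:
    """Fraction of co-bound genes whose factor-A and factor-B sites lie
    within ``threshold_bp``; genes missing peaks for either factor are
    skipped and reported in the returned count."""
    n_within = n_total = n_skipped = 0
    for gene in shared_genes:
        pa = peaks_by_gene_a.get(gene)
        pb = peaks_by_gene_b.get(gene)
        if not pa or not pb:
            n_skipped += 1
            continue
        n_total += 1
        if site_distance(pa, pb) < threshold_bp:
            n_within += 1
    if n_total == 0:
        raise ChipdynError("no co-bound genes with peaks for both factors")
    return n_within / n_total, n_skipped


def classify_rela_dependence(
    gene_id: str, wt_bits: Sequence[int], ko_bits: Sequence[int]
) -> DependenceCall:
    """Classify Sirt6-binding dependence on RelA from WT vs RelA-null occupancy.

    abrogated: no occupancy left in the knockout; reduced: occupancy at >= 1
    but strictly fewer timepoints than wild type; independent: at least as
    many.  Only binary occupancy is compared — ChIP efficiencies differ
    between genotypes, so score magnitudes are not.
    """
    if len(wt_bits) != len(ko_bits):
        raise ValidationError("WT and KO patterns must cover the same timepoints")
    n_wt = sum(int(b) for b in wt_bits)
    n_ko = sum(int(b) for b in ko_bits)
    if n_wt == 0:
        raise ValidationError(f"{gene_id}: gene is not Sirt6-bound in WT")
    if n_ko == 0:
        label = "abrogated"
    elif n_ko < n_wt:
        label = "reduced"
    else:
        label = "independent"
    return DependenceCall(gene_id, label)


def dependence_fractions(
    wt_occupancy: pd.DataFrame, ko_occupancy: pd.DataFrame, genes: Iterable[str]
) -> pd.Series:
    """Per-label fractions of dependence calls over ``genes`` that are
    WT-bound at >= 1 timepoint (others are skipped)."""
    calls = []
    for gene in genes:
        wt = wt_occupancy.loc[gene].to_numpy()
        if wt.sum() == 0:
            continue
        ko = ko_occupancy.loc[gene].to_numpy()
        calls.append(classify_rela_dependence(gene, wt, ko).label)
    if not calls:
        raise ChipdynError("no WT-bound genes to classify")
    counts = pd.Series(calls).value_counts()
    return (counts / counts.sum()).reindex(
        ["abrogated", "reduced", "independent"], fill_value=0.0
    )
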