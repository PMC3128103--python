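"""End-to-end orchestration of the occupancy analysis.

``process_chip`` runs normalization → peak calling → permutation FDR →
gene-level target mapping → knockout-control subtraction → per-factor
unions for a whole sample design.  ``run_synthetic_study`` drives the full
analysis on generated data and scores every recovered quantity against the
planted truth; it is the package's main self-check and the workhorse of the
acceptance evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .epistasis import EpistasisRuleParams, classify_all, filter_expressed, normalize_to_reference
from .occupancy import (
    dependence_fractions,
    fraction_within,
    overlap_hypergeometric,
)
from .peaks import call_peaks, estimate_fdr, normalize_biweight
from .simulate import (
    GroundTruth,
    SIRT6_TIMEPOINTS,
    SimulationParams,
    simulate_chip_signals,
    simulate_expression,
    simulate_truth,
    simulate_universe,
)
from .targets import peaks_to_genes, subtract_knockout_control, union_over_timepoints
from .types import Peak, PromoterAnnotation, SampleKey, TargetSet

CONTROL_GENOTYPE = {"Sirt6": "Sirt6KO", "RelA": "RelAKO"}


@dataclass
class ChipResult:
    """Called peaks and target sets for one sample design."""

    peaks: dict[SampleKey, list[Peak]]
    raw_targets: dict[SampleKey, TargetSet]
    targets: dict[SampleKey, TargetSet] = field(default_factory=dict)
    unions: dict[tuple[str, str], TargetSet] = field(default_factory=dict)

    def passing_peaks_by_gene(
        self, factor: str, genotype: str, fdr_threshold: float
    ) -> dict[str, list[Peak]]:
        """FDR-passing peaks pooled over a factor/genotype's timepoints, by gene."""
        out: dict[str, list[Peak]] = {}
        for sample, peaks in self.peaks.items():
            if sample.factor != factor or sample.genotype != genotype:
                continue
            for p in peaks:
                if p.fdr <= fdr_threshold:
                    out.setdefault(p.gene_id, []).append(p)
        return out


def process_sample(
    probes: pd.DataFrame,
    annotations: Mapping[str, PromoterAnnotation],
    sample: SampleKey,
    config: PipelineConfig,
    seed,
) -> tuple[list[Peak], TargetSet]:
    """Normalize one sample, call peaks, attach FDR, and map to genes."""
    norm = normalize_biweight(probes)
    peaks = call_peaks(norm, config.window_bp, config.min_probes, config.score_threshold)
    peaks = estimate_fdr(
        peaks, norm, config.n_permutations, seed,
        config.window_bp, config.min_probes, config.score_threshold,
    )
    targets = peaks_to_genes(
        peaks, annotations, sample, config.fdr_threshold(sample.factor), config.flank_bp
    )
    return peaks, targets


def process_chip(
    signals: Mapping[SampleKey, pd.DataFrame],
    annotations: Mapping[str, PromoterAnnotation],
    config: PipelineConfig,
) -> ChipResult:
    """Run the ChIP side of the pipeline for every sample in ``signals``.

    Per-sample FDR permutation seeds are derived deterministically from
    ``config.seed`` and the sample's position in sorted key order.
    """
    order = sorted(signals, key=str)
    peaks: dict[SampleKey, list[Peak]] = {}
    raw: dict[SampleKey, TargetSet] = {}
    for i, sample in enumerate(order):
        pk, ts = process_sample(signals[sample], annotations, sample, config, [config.seed, i])
        peaks[sample] = pk
        raw[sample] = ts

    result = ChipResult(peaks, raw)
    for sample, ts in raw.items():
        control = CONTROL_GENOTYPE[sample.factor]
        if sample.genotype == control:
            continue  # the negative control itself
        ctrl_key = SampleKey(sample.assay, sample.factor, control, sample.timepoint)
        if ctrl_key in raw:
            ts = subtract_knockout_control(ts, raw[ctrl_key])
        result.targets[sample] = ts
    for (factor, genotype) in sorted({(s.factor, s.genotype) for s in result.targets}):
        members = [
            ts for s, ts in result.targets.items()
            if s.factor == factor and s.genotype == genotype
        ]
        result.unions[(factor, genotype)] = union_over_timepoints(members)
    return result


def occupancy_frame(
    result: ChipResult, factor: str, genotype: str, genes, timepoints
) -> pd.DataFrame:
    """Genes × timepoints 0/1 occupancy from control-subtracted target sets."""
    idx = pd.Index(genes, name="gene_id")
    cols = {}
    for t in timepoints:
        key = SampleKey("chip", factor, genotype, t)
        cols[t] = idx.isin(result.targets[key].genes).astype(np.int8)
    return pd.DataFrame(cols, index=idx)


@dataclass
class StudyResult:
    """Everything the synthetic study recovers, next to its planted truth."""

    truth: GroundTruth
    chip: ChipResult
    metrics: dict[str, float]
    expression: pd.DataFrame | None = None
    epistasis_calls: pd.Series | None = None


def run_synthetic_study(
    params: SimulationParams,
    config: PipelineConfig,
    with_expression: bool = True,
) -> StudyResult:
    """Generate a dataset, run the full analysis, and score it against truth.

    Metrics (all computed, never planted):

    * ``sensitivity`` / ``false_discovery_proportion`` — per-(gene, timepoint)
      Sirt6 WT occupancy calls vs planted occupancy bits.
    * ``frac_shared_recovered`` — |Sirt6 ∩ RelA| / |RelA| over recovered
      per-factor target unions.
    * ``cooccupancy_log10_p`` — hypergeometric tail for that overlap.
    * ``frac_abrogated_recovered`` — abrogated share of recovered co-bound
      genes, from WT vs RelA-null occupancy patterns.
    * ``frac_within_500bp_recovered`` — close-site share of recovered
      co-bound genes, from called peak centres.
    * ``epistasis_accuracy`` — planted class recovered on expressed co-bound
      genes (planted Neutral counts as correctly recovered when the
      classifier returns Unclassified).
    """
    annotations = simulate_universe(params)
    truth = simulate_truth(params, annotations)
    signals = simulate_chip_signals(truth, params)
    chip = process_chip(signals, annotations, config)
    genes = truth.genes
    metrics: dict[str, float] = {}

    # --- per-timepoint sensitivity / FDP for Sirt6 in WT
    occ_called = occupancy_frame(chip, "Sirt6", "WT", genes, SIRT6_TIMEPOINTS)
    occ_true = truth.occupancy[("Sirt6", "WT")]
    called = occ_called.to_numpy(dtype=bool)
    planted = occ_true.to_numpy(dtype=bool)
    metrics["sensitivity"] = float((called & planted).sum() / planted.sum())
    n_called = called.sum()
    metrics["false_discovery_proportion"] = (
        float((called & ~planted).sum() / n_called) if n_called else 0.0
    )

    # --- co-occupancy of the recovered target universes
    s6_union = chip.unions[("Sirt6", "WT")]
    rela_union = chip.unions[("RelA", "WT")]
    shared = s6_union.genes & rela_union.genes
    metrics["n_sirt6_targets"] = float(len(s6_union))
    metrics["n_rela_targets"] = float(len(rela_union))
    metrics["n_shared"] = float(len(shared))
    metrics["frac_shared_recovered"] = (
        len(shared) / len(rela_union) if len(rela_union) else float("nan")
    )
    test = overlap_hypergeometric(s6_union.genes, rela_union.genes, genes)
    metrics["cooccupancy_log10_p"] = test.log10_p

    # --- RelA dependence of Sirt6 occupancy on recovered co-bound genes
    occ_ko = occupancy_frame(chip, "Sirt6", "RelAKO", genes, SIRT6_TIMEPOINTS)
    dep = dependence_fractions(occ_called, occ_ko, sorted(shared))
    metrics["frac_abrogated_recovered"] = float(dep["abrogated"])
    metrics["frac_reduced_recovered"] = float(dep["reduced"])

    # --- site distances on recovered co-bound genes
    s6_peaks = chip.passing_peaks_by_gene("Sirt6", "WT", config.fdr_threshold_sirt6)
    rela_peaks = chip.passing_peaks_by_gene("RelA", "WT", config.fdr_threshold_rela)
    frac_within, _ = fraction_within(sorted(shared), s6_peaks, rela_peaks, 500)
    metrics["frac_within_500bp_recovered"] = frac_within

    expression = None
    calls = None
    if with_expression:
        expression = simulate_expression(truth, params)
        expressed = filter_expressed(expression, params.detection_floor)
        folds = normalize_to_reference(expressed)
        rules = EpistasisRuleParams(config.up_fold, config.down_fold)
        calls = classify_all(folds, rules)
        planted_cls = truth.info.loc[calls.index, "epistasis_class"].replace(
            {"Neutral": "Unclassified"}
        )
        eval_genes = truth.info.loc[calls.index, "shared"]
        if eval_genes.any():
            metrics["epistasis_accuracy"] = float(
                (calls[eval_genes] == planted_cls[eval_genes]).mean()
            )
        metrics["n_expressed"] = float(len(folds))

    return StudyResult(truth, chip, metrics, expression, calls)
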