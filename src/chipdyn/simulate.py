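"""Synthetic promoter tiling-array data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a universe of non-overlapping promoter windows (−3250..+750 bp
around each TSS, probes every 100 bp), factor-binding events rendered as
~500 bp-wide triangular enrichment bumps on a Gaussian log2-ratio noise
floor, oscillatory occupancy over a TNF-α time course (on at 15 min,
largely off at 30, rebound at 60), partial Sirt6/RelA co-occupancy with a
planted RelA-dependent fraction, knockout-control samples that carry no
specific signal, and genotype×time expression profiles following rule-based
epistasis class templates.

Every quantity that the analysis later estimates — co-occupancy fraction,
RelA-dependence fraction, site-distance distribution, occupancy dynamics,
epistasis class mixture — is planted here as an explicit parameter, so each
stage can be tested against known truth.  All randomness flows from
``SimulationParams.seed``; identical parameters give bitwise-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    ChipdynError,
    PromoterAnnotation,
    SampleKey,
    TILED_WINDOW,
)


class ParameterError(ChipdynError):
    """Simulation parameters are inconsistent or out of range."""


DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    # Mixture over Sirt6/RelA co-bound genes.  The antagonistic classes
    # (AllUp + TNFUp + ZeroUp) sum to 0.63, matching the observed share of
    # antagonistically regulated genes among expressed co-bound targets
    # (301/480); the per-class split is a design choice.
    "AllUp": 0.25,
    "TNFUp": 0.30,
    "ZeroUp": 0.08,
    "Inverse": 0.10,
    "RelABlockedSirt6": 0.07,
    "Neutral": 0.20,
}

SIRT6_TIMEPOINTS = (0, 15, 30, 60)
RELA_TIMEPOINTS = (0, 15, 30)  # the 60-min RelA ChIP is not part of the design


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults are the study conditions.

    Fractions of the promoter universe: ``frac_rela_targets`` (~2738/21249),
    ``frac_sirt6_targets`` (~5050/21249), ``frac_sirt6_baseline``
    (~1899/21249).  Conditional fractions: ``frac_shared`` (co-bound share of
    RelA targets, 1481/2738), ``frac_rela_dependent`` (abrogated share of
    co-bound genes, 0.49), ``frac_within_500bp`` (close-site share of
    co-bound genes, 0.65), ``frac_vacated`` (baseline Sirt6 targets unbound
    at every post-TNF timepoint, 684/1899).
    """

    n_genes: int = 5000
    probe_spacing: int = 100
    # binding structure
    frac_rela_targets: float = 0.13
    frac_sirt6_targets: float = 0.238
    frac_sirt6_baseline: float = 0.09
    frac_vacated: float = 0.36
    frac_shared: float = 0.54
    frac_rela_dependent: float = 0.49
    frac_rela_reduced: float = 0.20
    frac_within_500bp: float = 0.65
    # per-timepoint occupancy of RelA targets (13% bound unstimulated,
    # 91% under TNF, partial redistribution at 30 min)
    rela_t0_occupancy: float = 0.13
    rela_t15_occupancy: float = 0.91
    rela_t30_occupancy: float = 0.50
    # signal rendering
    peak_height: float = 1.5
    fragment_width: int = 500
    noise_sd: float = 0.3
    # expression
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_size: float = 2.0
    wt_tnf_fold: float = 3.0
    expression_noise_sd: float = 0.10
    detection_floor: float = 100.0
    frac_below_floor: float = 0.676  # 1 - 480/1481 co-bound genes expressed
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_rela_targets", "frac_sirt6_targets", "frac_sirt6_baseline",
            "frac_vacated", "frac_shared", "frac_rela_dependent",
            "frac_rela_reduced", "frac_within_500bp", "rela_t0_occupancy",
            "rela_t15_occupancy", "rela_t30_occupancy", "frac_below_floor",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {val}")
        if self.peak_height <= 0 or self.probe_spacing <= 0:
            raise ParameterError("peak_height and probe_spacing must be > 0")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.fragment_width <= 0:
            raise ParameterError("fragment_width must be > 0")
        if self.n_genes < 0:
            raise ParameterError("n_genes must be >= 0")
        if self.frac_sirt6_baseline > self.frac_sirt6_targets:
            raise ParameterError("frac_sirt6_baseline cannot exceed frac_sirt6_targets")
        if self.frac_shared * self.frac_rela_targets > self.frac_sirt6_targets:
            raise ParameterError(
                "frac_shared * frac_rela_targets exceeds frac_sirt6_targets: "
                "co-bound genes would outnumber Sirt6 targets"
            )
        if self.frac_rela_dependent + self.frac_rela_reduced > 1.0:
            raise ParameterError("frac_rela_dependent + frac_rela_reduced must be <= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class_proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - {
            "AllUp", "TNFUp", "ZeroUp", "Inverse", "RelABlockedSirt6", "Neutral"
        }
        if unknown:
            raise ParameterError(f"unknown epistasis class(es): {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth per gene, plus per-sample occupancy bit matrices.

    ``info`` columns: sirt6_target, rela_target, shared (bools),
    dependence ("abrogated"/"reduced"/"independent", "" if not co-bound),
    sirt6_site / rela_site (TSS-relative bp, NaN if unbound),
    epistasis_class.  ``occupancy[(factor, genotype)]`` is a genes×timepoint
    0/1 DataFrame; knockout-control samples (Sirt6 IP in Sirt6KO, RelA IP in
    RelAKO) are identically zero and therefore not stored.
    """

    params: SimulationParams
    annotations: dict[str, PromoterAnnotation]
    info: pd.DataFrame
    occupancy: dict[tuple[str, str], pd.DataFrame]

    @property
    def genes(self) -> pd.Index:
        return self.info.index

    def bound_genes(self, factor: str, genotype: str, timepoint: int) -> frozenset[str]:
        occ = self.occupancy[(factor, genotype)]
        return frozenset(occ.index[occ[timepoint] == 1])


def _rng(params: SimulationParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stage])


def simulate_universe(params: SimulationParams) -> dict[str, PromoterAnnotation]:
    """Promoter universe: distinct ids, non-overlapping tiled windows, alternating strands."""
    annotations: dict[str, PromoterAnnotation] = {}
    per_chrom = 1000
    for i in range(params.n_genes):
        gene = f"g{i:06d}"
        chrom = f"chr{i // per_chrom + 1}"
        tss = 50_000 + (i % per_chrom) * 10_000  # windows span 4 kb; 10 kb spacing
        strand = "+" if i % 2 == 0 else "-"
        annotations[gene] = PromoterAnnotation(gene, chrom, tss, strand)
    return annotations


def _site_range() -> tuple[int, int]:
    # keep the full triangular bump support inside the tiled window
    lo, hi = TILED_WINDOW
    return lo + 500, hi - 1 - 500


def simulate_truth(
    params: SimulationParams, annotations: dict[str, PromoterAnnotation]
) -> GroundTruth:
    """Plant binding structure: target sets, occupancy patterns, sites, classes.

    Memberships are independent Bernoulli draws, so realized fractions match
    the parameters to within binomial sampling error.  Temporal patterns:
    baseline Sirt6 targets either vacate after TNF (1,0,0,0) or follow the
    oscillation (1,1,0,1) / stay constitutive (1,1,1,1); induced targets are
    mostly periodic (0,1,0,1) with late-only and transient minorities.  In
    RelA-null cells, "abrogated" co-bound genes lose all Sirt6 occupancy,
    "reduced" genes lose one bound timepoint, all others are unchanged.
    """
    rng = _rng(params, 1)
    genes = pd.Index(list(annotations), name="gene_id")
    n = len(genes)

    rela_target = rng.random(n) < params.frac_rela_targets
    shared = rela_target & (rng.random(n) < params.frac_shared)
    # Sirt6 targets = co-bound genes plus extra targets outside the RelA set,
    # thinned so the total Sirt6 fraction matches frac_sirt6_targets.
    p_joint = params.frac_shared * params.frac_rela_targets
    denom = 1.0 - params.frac_rela_targets
    p_extra = (params.frac_sirt6_targets - p_joint) / denom if denom > 0 else 0.0
    if not 0.0 <= p_extra <= 1.0:
        raise ParameterError(
            "cannot realize frac_sirt6_targets given frac_rela_targets and frac_shared"
        )
    sirt6_target = shared | (~rela_target & (rng.random(n) < p_extra))

    # --- Sirt6 WT occupancy over (0, 15, 30, 60)
    p_base = (
        params.frac_sirt6_baseline / params.frac_sirt6_targets
        if params.frac_sirt6_targets > 0
        else 0.0
    )
    baseline = sirt6_target & (rng.random(n) < p_base)
    vacated = baseline & (rng.random(n) < params.frac_vacated)
    occ_s6 = np.zeros((n, 4), dtype=np.int8)
    occ_s6[vacated] = (1, 0, 0, 0)
    retained = baseline & ~vacated
    osc = rng.random(n) < 0.7
    occ_s6[retained & osc] = (1, 1, 0, 1)
    occ_s6[retained & ~osc] = (1, 1, 1, 1)
    induced = sirt6_target & ~baseline
    u = rng.random(n)
    occ_s6[induced & (u < 0.7)] = (0, 1, 0, 1)
    occ_s6[induced & (u >= 0.7) & (u < 0.85)] = (0, 0, 0, 1)
    occ_s6[induced & (u >= 0.85)] = (0, 1, 0, 0)

    # --- RelA WT occupancy over (0, 15, 30)
    occ_rela = np.zeros((n, 3), dtype=np.int8)
    occ_rela[rela_target, 0] = rng.random(rela_target.sum()) < params.rela_t0_occupancy
    occ_rela[rela_target, 1] = rng.random(rela_target.sum()) < params.rela_t15_occupancy
    occ_rela[rela_target, 2] = rng.random(rela_target.sum()) < params.rela_t30_occupancy
    silent = rela_target & (occ_rela.sum(axis=1) == 0)
    occ_rela[silent, 1] = 1  # every planted target binds somewhere

    # --- RelA dependence of Sirt6 binding (co-bound genes)
    dependence = np.array([""] * n, dtype=object)
    d = rng.random(n)
    abrogated = shared & (d < params.frac_rela_dependent)
    rest = shared & ~abrogated
    p_red = (
        params.frac_rela_reduced / (1.0 - params.frac_rela_dependent)
        if params.frac_rela_dependent < 1.0
        else 0.0
    )
    wants_reduced = rest & (rng.random(n) < p_red)
    # "reduced" (bound at >=1 but strictly fewer timepoints) needs >=2 bound
    # WT timepoints to be realizable; singly-bound genes stay independent.
    reduced = wants_reduced & (occ_s6.sum(axis=1) >= 2)
    independent = shared & ~abrogated & ~reduced
    dependence[abrogated] = "abrogated"
    dependence[reduced] = "reduced"
    dependence[independent] = "independent"

    occ_s6_ko = occ_s6.copy()
    occ_s6_ko[abrogated] = 0
    for idx in np.flatnonzero(reduced):
        bound = np.flatnonzero(occ_s6_ko[idx])
        occ_s6_ko[idx, rng.choice(bound)] = 0

    # --- binding sites (TSS-relative offsets)
    lo, hi = _site_range()
    sirt6_site = np.full(n, np.nan)
    rela_site = np.full(n, np.nan)
    rela_site[rela_target] = rng.integers(lo, hi + 1, rela_target.sum())
    solo = sirt6_target & ~shared
    sirt6_site[solo] = rng.integers(lo, hi + 1, solo.sum())
    # co-bound genes: plant the site distance with a resolution buffer around
    # the 500 bp cut (close pairs < 400 bp, far pairs > 700 bp), so the
    # planted within-500bp fraction is well defined after peak-center jitter.
    for idx in np.flatnonzero(shared):
        base = rela_site[idx]
        if rng.random() < params.frac_within_500bp:
            dist = rng.uniform(0, 400)
        else:
            room = max(base - lo, hi - base)
            dist = rng.uniform(700, min(2000, room))
        sides = [s for s in (-1, 1) if lo <= base + s * dist <= hi]
        side = sides[0] if len(sides) == 1 else sides[int(rng.random() < 0.5)]
        sirt6_site[idx] = round(base + side * dist)

    # --- epistasis classes: mixture over co-bound genes, Neutral elsewhere
    labels = list(params.class_proportions)
    probs = np.array([params.class_proportions[k] for k in labels])
    epi = np.array(["Neutral"] * n, dtype=object)
    epi[shared] = rng.choice(labels, size=int(shared.sum()), p=probs)

    info = pd.DataFrame(
        {
            "sirt6_target": sirt6_target,
            "rela_target": rela_target,
            "shared": shared,
            "dependence": dependence,
            "sirt6_site": sirt6_site,
            "rela_site": rela_site,
            "epistasis_class": epi,
        },
        index=genes,
    )
    occupancy = {
        ("Sirt6", "WT"): pd.DataFrame(occ_s6, index=genes, columns=list(SIRT6_TIMEPOINTS)),
        ("Sirt6", "RelAKO"): pd.DataFrame(
            occ_s6_ko, index=genes, columns=list(SIRT6_TIMEPOINTS)
        ),
        ("RelA", "WT"): pd.DataFrame(occ_rela, index=genes, columns=list(RELA_TIMEPOINTS)),
    }
    return GroundTruth(params, annotations, info, occupancy)


def design_samples() -> list[SampleKey]:
    """The default ChIP design: each factor in WT, its knockout control, and
    Sirt6 additionally in RelA-null cells."""
    samples = []
    for t in SIRT6_TIMEPOINTS:
        samples.append(SampleKey("chip", "Sirt6", "WT", t))
        samples.append(SampleKey("chip", "Sirt6", "Sirt6KO", t))
        samples.append(SampleKey("chip", "Sirt6", "RelAKO", t))
    for t in RELA_TIMEPOINTS:
        samples.append(SampleKey("chip", "RelA", "WT", t))
        samples.append(SampleKey("chip", "RelA", "RelAKO", t))
    return samples


def probe_grid(params: SimulationParams) -> np.ndarray:
    lo, hi = TILED_WINDOW
    return np.arange(lo, hi, params.probe_spacing)


def simulate_chip_signals(
    truth: GroundTruth, params: SimulationParams | None = None
) -> dict[SampleKey, pd.DataFrame]:
    """Render probe-level log2 ratios for every sample in the design.

    Signal model: iid Gaussian noise N(0, noise_sd) per probe, plus — for
    genes bound in that sample — a triangular bump of height ``peak_height``
    and half-width ``fragment_width`` centred on the planted site.
    Knockout-control samples (Sirt6 IP in Sirt6-null cells; RelA IP in
    RelA-null cells) carry noise only.
    """
    params = params or truth.params
    rng = _rng(params, 2)
    genes = truth.genes
    n = len(genes)
    grid = probe_grid(params)
    p = len(grid)
    probe_ids = np.array(
        [f"{g}_p{i:02d}" for g in genes for i in range(p)], dtype=object
    )
    gene_col = np.repeat(np.asarray(genes, dtype=object), p)
    offset_col = np.tile(grid, n)

    out: dict[SampleKey, pd.DataFrame] = {}
    for sample in design_samples():
        values = rng.normal(0.0, params.noise_sd, size=(n, p))
        is_control = (sample.factor == "Sirt6" and sample.genotype == "Sirt6KO") or (
            sample.factor == "RelA" and sample.genotype == "RelAKO"
        )
        if not is_control:
            occ = truth.occupancy[(sample.factor, sample.genotype)]
            bound = occ[sample.timepoint].to_numpy(dtype=bool)
            site = truth.info[
                "sirt6_site" if sample.factor == "Sirt6" else "rela_site"
            ].to_numpy()
            rows = np.flatnonzero(bound)
            if len(rows):
                kern = np.clip(
                    1.0 - np.abs(grid[None, :] - site[rows, None]) / params.fragment_width,
                    0.0,
                    None,
                )
                values[rows] += params.peak_height * kern
        out[sample] = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene_id": gene_col,
                "offset": offset_col,
                "log2_ratio": values.ravel(),
            }
        )
    return out


_EXPRESSION_GENOTYPES = ("WT", "Sirt6KO", "DKO")
_EXPRESSION_TIMEPOINTS = (0, 90)


def class_template(label: str, effect_size: float, wt_tnf_fold: float) -> pd.Series:
    """Noise-free fold-change template (relative to WT t=0) for one class."""
    e, f = effect_size, wt_tnf_fold
    wt = {0: 1.0, 90: f}
    tmpl = {
        "Neutral": {"Sirt6KO": wt, "DKO": wt},
        "AllUp": {"Sirt6KO": {0: e, 90: e * f}, "DKO": wt},
        "TNFUp": {"Sirt6KO": {0: 1.0, 90: e * f}, "DKO": wt},
        "ZeroUp": {"Sirt6KO": {0: e, 90: f}, "DKO": wt},
        "Inverse": {"Sirt6KO": {0: 1.0 / e, 90: f / e}, "DKO": {0: e, 90: e * f}},
        "RelABlockedSirt6": {"Sirt6KO": {0: e, 90: f}, "DKO": {0: e, 90: f}},
    }[label]
    data = {("WT", t): wt[t] for t in _EXPRESSION_TIMEPOINTS}
    for geno in ("Sirt6KO", "DKO"):
        for t in _EXPRESSION_TIMEPOINTS:
            data[(geno, t)] = tmpl[geno][t]
    cols = pd.MultiIndex.from_tuples(sorted(data), names=["genotype", "timepoint"])
    return pd.Series({c: data[c] for c in cols}).reindex(cols)


def simulate_expression(
    truth: GroundTruth, params: SimulationParams | None = None
) -> pd.DataFrame:
    """Detection-value matrix over {WT, Sirt6KO, DKO} × {0, 90} minutes.

    Each gene's class template is scaled by a per-gene baseline detection and
    multiplied by lognormal noise.  A ``frac_below_floor`` fraction of genes
    gets a baseline low enough that every sample stays under the detection
    floor (these model the co-bound targets whose expression the arrays
    cannot detect); the rest sit comfortably above it.
    """
    params = params or truth.params
    rng = _rng(params, 3)
    genes = truth.genes
    n = len(genes)
    cols = pd.MultiIndex.from_tuples(
        [(g, t) for g in _EXPRESSION_GENOTYPES for t in _EXPRESSION_TIMEPOINTS],
        names=["genotype", "timepoint"],
    )
    templates = {
        label: class_template(label, params.effect_size, params.wt_tnf_fold)
        .reindex(cols)
        .to_numpy()
        for label in ("Neutral", "AllUp", "TNFUp", "ZeroUp", "Inverse", "RelABlockedSirt6")
    }
    tmpl = np.vstack([templates[c] for c in truth.info["epistasis_class"]])

    below = rng.random(n) < params.frac_below_floor
    floor = params.detection_floor
    baseline = np.empty(n)
    # sub-floor genes: even the largest template cell stays ~40% under floor
    max_fold = tmpl.max(axis=1)
    baseline[below] = floor / max_fold[below] * rng.uniform(0.2, 0.6, below.sum())
    baseline[~below] = floor * np.exp(rng.uniform(np.log(2.5), np.log(20), (~below).sum()))

    noise = np.exp(rng.normal(0.0, params.expression_noise_sd, size=(n, len(cols))))
    values = baseline[:, None] * tmpl * noise
    return pd.DataFrame(values, index=genes, columns=cols)
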