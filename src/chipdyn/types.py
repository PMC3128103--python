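"""Shared domain types for promoter tiling-array occupancy analysis.

The analysis operates on promoter tiling arrays in which every gene is
represented by one window of probes around its transcription start site
(TSS), here −3250 bp upstream to +750 bp downstream.  Probe positions are
carried as signed, strand-oriented offsets from the TSS; called peaks are
carried as 0-based half-open intervals in *window coordinates*, i.e.
relative to the upstream edge of the tiled window (offset −3250 maps to
window coordinate 0).  Genomic BED output converts window coordinates
strand-awareness back to chromosome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Tiled window around each TSS, in strand-oriented bp: [upstream, downstream)
TILED_WINDOW: tuple[int, int] = (-3250, 750 + 1)  # probes may sit at +750
WINDOW_ORIGIN: int = TILED_WINDOW[0]  # offset that maps to window coordinate 0
WINDOW_SPAN: int = TILED_WINDOW[1] - TILED_WINDOW[0]

CHIP_TIMEPOINTS: tuple[int, ...] = (0, 15, 30, 60)
EXPRESSION_TIMEPOINTS: tuple[int, ...] = (0, 90)

FACTORS = ("Sirt6", "RelA", "none")
GENOTYPES = ("WT", "Sirt6KO", "RelAKO", "DKO")
ASSAYS = ("chip", "expression")


class ChipdynError(Exception):
    """Base class for package errors."""


class FormatError(ChipdynError):
    """Malformed input file (missing column, bad header)."""


class ValidationError(ChipdynError):
    """A value violates a domain invariant."""


class ConfigError(ChipdynError):
    """Invalid configuration key or value."""


class LookupGeneError(ChipdynError):
    """A gene identifier is absent from the annotation universe."""


@dataclass(frozen=True, slots=True)
class PromoterAnnotation:
    """One promoter per gene: TSS position and strand on a chromosome."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValidationError(f"tss must be >= 0, got {self.tss}")


@dataclass(frozen=True, slots=True)
class SampleKey:
    """Identifies one array sample: assay, IP'd factor, genotype, timepoint.

    ChIP samples name the immunoprecipitated factor; expression samples have
    factor "none".  Timepoints are minutes after TNF-α addition and must be
    drawn from the assay's design grid.
    """

    assay: str
    factor: str
    genotype: str
    timepoint: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.factor not in FACTORS:
            raise ValidationError(f"unknown factor {self.factor!r}")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.assay == "chip":
            if self.factor == "none":
                raise ValidationError("chip samples must name an IP'd factor")
            allowed = CHIP_TIMEPOINTS
        else:
            if self.factor != "none":
                raise ValidationError("expression samples have factor='none'")
            allowed = EXPRESSION_TIMEPOINTS
        if self.timepoint not in allowed:
            raise ValidationError(
                f"timepoint {self.timepoint} not in design grid {allowed} for {self.assay}"
            )

    def __str__(self) -> str:
        return f"{self.assay}:{self.factor}:{self.genotype}:{self.timepoint}"

    @classmethod
    def parse(cls, text: str) -> "SampleKey":
        parts = text.split(":")
        if len(parts) != 4:
            raise FormatError(f"sample key must be assay:factor:genotype:timepoint, got {text!r}")
        assay, factor, genotype, timepoint = parts
        return cls(assay, factor, genotype, int(timepoint))


@dataclass(frozen=True, slots=True)
class Peak:
    """A called enrichment interval within one promoter's tiled window.

    ``start``/``end`` are 0-based half-open window coordinates (0 is the
    upstream edge of the tiled window); ``score`` is the mean normalized
    log2 ratio over member probes; ``fdr`` the permutation-FDR estimate.
    """

    gene_id: str
    start: int
    end: int
    score: float
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"peak must have start < end, got [{self.start}, {self.end})")
        if self.fdr == self.fdr and not 0.0 <= self.fdr <= 1.0:  # NaN-safe
            raise ValidationError(f"fdr must be in [0, 1], got {self.fdr}")
        if self.score != self.score or self.score in (float("inf"), float("-inf")):
            raise ValidationError("peak score must be finite")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TargetSet:
    """Gene-level target calls for one sample (or a union over timepoints).

    ``timepoint_label`` is the sample's timepoint as a string, or "any" for
    unions over a time course.
    """

    factor: str
    genotype: str
    timepoint_label: str
    genes: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_sample(cls, sample: SampleKey, genes) -> "TargetSet":
        return cls(sample.factor, sample.genotype, str(sample.timepoint), frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True, slots=True)
class DependenceCall:
    """RelA-dependence of a gene's Sirt6 occupancy: abrogated / reduced / independent."""

    gene_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("abrogated", "reduced", "independent"):
            raise ValidationError(f"unknown dependence label {self.label!r}")


@dataclass(frozen=True, slots=True)
class EpistasisCall:
    """Rule-based epistasis class of a gene's genotype×time expression profile."""

    gene_id: str
    label: str

    ANTAGONISTIC = ("AllUp", "TNFUp", "ZeroUp")
    LABELS = ("AllUp", "TNFUp", "ZeroUp", "Inverse", "RelABlockedSirt6", "Unclassified")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise ValidationError(f"unknown epistasis label {self.label!r}")

    @property
    def antagonistic(self) -> bool:
        return self.label in self.ANTAGONISTIC
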