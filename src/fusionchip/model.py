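"""Domain types for exon-junction fusion-gene arrays.

A fusion gene joins a 5' partner *A* to a 3' partner *B*; the chimeric
transcript retains exons ``1..i`` of A and exons ``j..n_B`` of B.  The array
interrogates each candidate with two probe families:

* **chimeric** probes spanning every possible exon-exon junction (i, j) —
  laid out as an ``n_A x n_B`` heatmap, and
* **intragenic** probes targeting every exon of each partner — the per-exon
  expression profile whose discontinuity at the breakpoint corroborates the
  chimeric signal.

All exon indices are 1-based, matching the "13-3" style breakpoint labels
used when reporting calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FusionChipError",
    "FormatError",
    "ValidationError",
    "MissingProbeError",
    "AssemblyError",
    "DesignError",
    "Tag",
    "ProbeType",
    "TranscriptVariant",
    "FusionCandidate",
    "ProbeAnnotation",
    "IntensityTable",
    "ChimericHeatmap",
    "IntragenicProfile",
    "ScoringParams",
    "BreakpointScore",
    "FusionScoreResult",
]


class FusionChipError(Exception):
    """Base class for all package errors."""


class FormatError(FusionChipError):
    """A file does not conform to the documented TSV/FASTA layout."""


class ValidationError(FusionChipError):
    """Input violates a domain invariant (bad value, inconsistent reference)."""


class MissingProbeError(ValidationError):
    """An intensity table lacks probes that the annotation requires."""

    def __init__(self, probe_ids: Sequence[str]):
        self.probe_ids = tuple(sorted(probe_ids))
        preview = ", ".join(self.probe_ids[:10])
        more = "" if len(self.probe_ids) <= 10 else f" (+{len(self.probe_ids) - 10} more)"
        super().__init__(f"intensity table is missing {len(self.probe_ids)} annotated probe(s): {preview}{more}")


class AssemblyError(FusionChipError):
    """A heatmap or profile cannot be assembled (missing exon-exon combination)."""


class DesignError(FusionChipError):
    """Probe design failed (missing exon record, degenerate sequence)."""


class Tag(str, Enum):
    """Per-row/column annotation produced by the half-binder filter."""

    NONE = "none"
    ZEROED = "zeroed"
    WEAK = "weak_half_binding"


class ProbeType(str, Enum):
    CHIMERIC = "chimeric"
    INTRAGENIC = "intragenic"


# Separator used to encode a (gene_a, gene_b) or (variant_a, variant_b) pair
# in the single gene/variant_id columns of chimeric annotation rows.
PAIR_SEP = "::"


@dataclass(frozen=True)
class TranscriptVariant:
    """One transcript model of a partner gene: an ordered list of exons."""

    gene_symbol: str
    variant_id: str
    n_exons: int
    exon_ids: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_exons < 1:
            raise ValidationError(f"{self.gene_symbol}/{self.variant_id}: n_exons must be >= 1")
        if not self.exon_ids:
            object.__setattr__(self, "exon_ids", tuple(str(k) for k in range(1, self.n_exons + 1)))
        if len(self.exon_ids) != self.n_exons:
            raise ValidationError(
                f"{self.gene_symbol}/{self.variant_id}: {len(self.exon_ids)} exon ids for n_exons={self.n_exons}"
            )
        if len(set(self.exon_ids)) != self.n_exons:
            raise ValidationError(f"{self.gene_symbol}/{self.variant_id}: exon ids are not unique")

    @property
    def key(self) -> str:
        return f"{self.gene_symbol}.{self.variant_id}"


@dataclass(frozen=True)
class FusionCandidate:
    """A candidate fusion A->B with one or more (variant_A, variant_B) pairs.

    The array probes only the A1+B2 constellation: exons 1..i of the 5'
    partner joined to exons j..n of the 3' partner.  Each variant pair gets
    its own chimeric heatmap; the candidate's score is the maximum over its
    pairs.
    """

    fusion_id: str
    variant_pairs: Tuple[Tuple[TranscriptVariant, TranscriptVariant], ...]

    def __post_init__(self):
        if not self.variant_pairs:
            raise ValidationError(f"{self.fusion_id}: candidate has no variant pairs")
        genes_a = {va.gene_symbol for va, _ in self.variant_pairs}
        genes_b = {vb.gene_symbol for _, vb in self.variant_pairs}
        if len(genes_a) != 1 or len(genes_b) != 1:
            raise ValidationError(f"{self.fusion_id}: inconsistent partner gene symbols across variant pairs")
        if self.gene_a == self.gene_b:
            raise ValidationError(f"{self.fusion_id}: 5' and 3' partner are the same gene")
        seen = set()
        for va, vb in self.variant_pairs:
            k = (va.variant_id, vb.variant_id)
            if k in seen:
                raise ValidationError(f"{self.fusion_id}: duplicate variant pair {k}")
            seen.add(k)

    @property
    def gene_a(self) -> str:
        return self.variant_pairs[0][0].gene_symbol

    @property
    def gene_b(self) -> str:
        return self.variant_pairs[0][1].gene_symbol


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe's placement on the array.

    Chimeric probes carry both exon indices and encode the two partners in
    ``gene``/``variant_id`` as ``"GENEA::GENEB"`` / ``"va::vb"``.  Intragenic
    probes carry a single gene/variant and exactly one exon index (``exon_a``
    when the gene is the candidate's 5' partner, ``exon_b`` when it is the 3'
    partner).
    """

    probe_id: str
    fusion_id: str
    probe_type: ProbeType
    gene: str
    variant_id: str
    exon_a: Optional[int] = None
    exon_b: Optional[int] = None

    def __post_init__(self):
        if self.probe_type is ProbeType.CHIMERIC:
            if self.exon_a is None or self.exon_b is None:
                raise ValidationError(f"probe {self.probe_id}: chimeric probes need both exon_a and exon_b")
            if PAIR_SEP not in self.gene or PAIR_SEP not in self.variant_id:
                raise ValidationError(
                    f"probe {self.probe_id}: chimeric probes encode partner pairs as 'A{PAIR_SEP}B'"
                )
        else:
            if (self.exon_a is None) == (self.exon_b is None):
                raise ValidationError(
                    f"probe {self.probe_id}: intragenic probes carry exactly one exon index"
                )
            if PAIR_SEP in self.gene:
                raise ValidationError(f"probe {self.probe_id}: intragenic probes carry a single gene")
        for e in (self.exon_a, self.exon_b):
            if e is not None and e < 1:
                raise ValidationError(f"probe {self.probe_id}: exon indices are 1-based")

    @property
    def gene_pair(self) -> Tuple[str, str]:
        a, _, b = self.gene.partition(PAIR_SEP)
        return (a, b)

    @property
    def variant_pair(self) -> Tuple[str, str]:
        a, _, b = self.variant_id.partition(PAIR_SEP)
        return (a, b)


@dataclass
class IntensityTable:
    """Raw probe intensities of one hybridized sample (fluorescence units)."""

    sample_id: str
    values: Mapping[str, float]

    def __post_init__(self):
        bad = [p for p, v in self.values.items() if v < 0 or not np.isfinite(v)]
        if bad:
            raise ValidationError(f"sample {self.sample_id}: negative/non-finite intensity for {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ChimericHeatmap:
    """Scores of all chimeric probes of one candidate's variant pair.

    ``matrix[i-1, j-1]`` is the score of the probe joining exon i of the 5'
    partner (last retained exon) to exon j of the 3' partner (first retained
    exon).
    """

    fusion_id: str
    variant_a: TranscriptVariant
    variant_b: TranscriptVariant
    matrix: np.ndarray
    row_tags: list = field(default_factory=list)
    col_tags: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.variant_a.n_exons, self.variant_b.n_exons):
            raise ValidationError(
                f"{self.fusion_id}: heatmap shape {self.matrix.shape} != "
                f"({self.variant_a.n_exons}, {self.variant_b.n_exons})"
            )
        if not self.row_tags:
            self.row_tags = [Tag.NONE] * self.matrix.shape[0]
        if not self.col_tags:
            self.col_tags = [Tag.NONE] * self.matrix.shape[1]
        if len(self.row_tags) != self.matrix.shape[0] or len(self.col_tags) != self.matrix.shape[1]:
            raise ValidationError(f"{self.fusion_id}: tag lengths do not match heatmap shape")

    def copy(self) -> "ChimericHeatmap":
        return ChimericHeatmap(
            fusion_id=self.fusion_id,
            variant_a=self.variant_a,
            variant_b=self.variant_b,
            matrix=self.matrix.copy(),
            row_tags=list(self.row_tags),
            col_tags=list(self.col_tags),
        )


@dataclass
class IntragenicProfile:
    """Per-exon scores of one partner-gene transcript variant."""

    gene: str
    variant_id: str
    exon_scores: np.ndarray

    def __post_init__(self):
        self.exon_scores = np.asarray(self.exon_scores, dtype=float)
        if self.exon_scores.ndim != 1 or self.exon_scores.size < 1:
            raise ValidationError(f"{self.gene}/{self.variant_id}: exon_scores must be a non-empty vector")

    @property
    def n_exons(self) -> int:
        return int(self.exon_scores.size)


@dataclass(frozen=True)
class ScoringParams:
    """All constants of the scoring, filtering and enhancement rules.

    Defaults are the published operating point: chimeric evidence capped at
    3.0, each partner's expression-break contribution capped at 1.5, the
    enhanced single-strong-probe sentinel 6.0 (3.0 under a weak half-binding
    tag), degenerate breakpoints scored 0.1, enhancement margin 0.8, and the
    half-binder triggers (25% of probes at 70%/50% of the line maximum, or
    three probes at/above the chimeric cutoff).
    """

    chimeric_cutoff: float = 3.0
    max_break_score: float = 1.5
    adjusted_to_max: float = 6.0
    weak_adjust_value: float = 3.0
    degenerate_score: float = 0.1
    enhancement_margin: float = 0.8
    halfbinder_fraction: float = 0.25
    halfbinder_level_strong: float = 0.70
    halfbinder_level_weak: float = 0.50
    halfbinder_count_trigger: int = 3

    def __post_init__(self):
        if not (0 < self.halfbinder_level_weak < self.halfbinder_level_strong <= 1):
            raise ValidationError("require 0 < halfbinder_level_weak < halfbinder_level_strong <= 1")
        for name in (
            "chimeric_cutoff",
            "max_break_score",
            "adjusted_to_max",
            "weak_adjust_value",
            "degenerate_score",
            "enhancement_margin",
            "halfbinder_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.adjusted_to_max < self.chimeric_cutoff:
            raise ValidationError("adjusted_to_max must be >= chimeric_cutoff")
        if self.halfbinder_count_trigger < 1:
            raise ValidationError("halfbinder_count_trigger must be >= 1")

    def replace(self, **kw) -> "ScoringParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class BreakpointScore:
    """Score of one candidate breakpoint (i, j) with its component terms.

    Segments: A1 = exons 1..i of A, A2 = exons i+1..n_A, B1 = exons 1..j-1
    of B, B2 = exons j..n_B; segment means are arithmetic means of the
    normalized exon scores (0 for an empty segment).
    """

    exon_a: int
    exon_b: int
    a1_mean: float
    a2_mean: float
    b1_mean: float
    b2_mean: float
    len_a1: int
    len_a2: int
    len_b1: int
    len_b2: int
    chimeric_value: float
    break_score_a: float
    break_score_b: float
    fusion_score: float


@dataclass
class FusionScoreResult:
    """Per-candidate outcome: the best breakpoint and the fusion score."""

    fusion_id: str
    best_breakpoint: BreakpointScore
    fusion_score: float
    rank: Optional[int] = None
    variant_a_id: str = ""
    variant_b_id: str = ""
    tags: Tuple[str, ...] = ()
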