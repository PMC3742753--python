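"""Intensity normalization, half-binder filtering, and probe enhancement.

Half-binders are chimeric probes whose single arm binds abundant cDNA on its
own, striping a whole row or column of the heatmap and mimicking fusion
evidence.  Rows/columns with pervasive high signal are therefore zeroed, and
moderately striped ones are tagged "weak half-binding" so that the
single-strong-probe enhancement is capped for them.

The enhancement step protects the converse signature: a genuine fusion often
shows exactly one outlier chimeric probe, which would otherwise be
outweighed by the intragenic evidence.  A lone maximum standing at least the
margin above the runner-up is promoted to the sentinel score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ChimericHeatmap,
    IntensityTable,
    ScoringParams,
    Tag,
    ValidationError,
)

__all__ = [
    "NormalizationConfig",
    "normalize_scores",
    "reference_probe_ids",
    "reduce_half_binders",
    "enhance_single_strong_probe",
]

_METHODS = ("log2_median_center", "log2_only", "none")


@dataclass(frozen=True)
class NormalizationConfig:
    """How raw fluorescence becomes a probe score.

    The default puts the bulk of (unexpressed) probes at score 0 and
    expresses signal as log2 fold change over the array median, the scale on
    which the cutoff constants (3.0, 6.0) read as "well above array median".
    """

    method: str = "log2_median_center"
    pseudocount: float = 1.0
    reference: str = "intragenic"

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValidationError(f"unknown normalization method {self.method!r}; choose from {_METHODS}")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.reference not in ("intragenic", "all"):
            raise ValidationError("reference must be 'intragenic' or 'all'")


def normalize_scores(
    raw: IntensityTable,
    config: NormalizationConfig | None = None,
    reference_ids=None,
) -> dict:
    """Convert raw intensities to probe scores.

    Default method: ``log2(intensity + pseudocount)``, median-centered,
    negatives floored at 0.  The centering median is taken over
    ``reference_ids`` when given, otherwise over all probes.  The scoring
    pipeline passes the intragenic probes as the reference: half-binding
    elevates chimeric probes specifically, so an all-probe median drifts
    upward on badly striped arrays while the intragenic baseline does not.

    Returns a ``probe_id -> score`` mapping.
    """
    config = config or NormalizationConfig()
    if len(raw) == 0:
        raise ValidationError(f"sample {raw.sample_id}: empty intensity table")
    probe_ids = list(raw.values.keys())
    v = np.asarray([raw.values[p] for p in probe_ids], dtype=float)
    if config.method == "none":
        s = v
    else:
        s = np.log2(v + config.pseudocount)
        if config.method == "log2_median_center":
            if reference_ids:
                ref = [raw.values[p] for p in probe_ids if p in reference_ids]
                if not ref:
                    raise ValidationError("no reference probes present in the intensity table")
                center = np.median(np.log2(np.asarray(ref, dtype=float) + config.pseudocount))
            else:
                center = np.median(s)
            s = np.maximum(s - center, 0.0)
    return dict(zip(probe_ids, s.tolist()))


def reference_probe_ids(annotations, config: NormalizationConfig | None = None):
    """The centering reference implied by ``config.reference`` (or None for 'all')."""
    from .model import ProbeType

    config = config or NormalizationConfig()
    if config.reference != "intragenic":
        return None
    return {a.probe_id for a in annotations if a.probe_type is ProbeType.INTRAGENIC}


def _line_decisions(line: np.ndarray, params: ScoringParams) -> tuple[bool, bool]:
    """(zero, weak) decision for one row or column, from its input values.

    A line whose maximum is 0 never triggers.  Both triggers require at
    least two qualifying probes so that a lone strong probe — the very
    signature the enhancement step protects — cannot zero or tag its own
    line.
    """
    mx = float(line.max())
    if mx <= 0:
        return False, False
    n = line.size
    n_strong = int(np.count_nonzero(line >= params.halfbinder_level_strong * mx))
    n_cutoff = int(np.count_nonzero(line >= params.chimeric_cutoff))
    zero = (n_strong >= 2 and n_strong >= params.halfbinder_fraction * n) or (
        n_cutoff >= params.halfbinder_count_trigger
    )
    n_weak = int(np.count_nonzero(line >= params.halfbinder_level_weak * mx))
    weak = n_weak >= 2 and n_weak >= params.halfbinder_fraction * n
    return zero, weak


def reduce_half_binders(hm: ChimericHeatmap, params: ScoringParams | None = None) -> ChimericHeatmap:
    """Zero striped rows/columns and tag moderately striped ones.

    A row or column is zeroed when at least 25% of its probes (and at least
    two) score at or above 70% of its maximum, or when three or more probes
    reach the chimeric cutoff.  Among the surviving lines, those where at
    least 25% of probes (and at least two) reach 50% of the maximum are
    tagged weak-half-binding.  All decisions are evaluated simultaneously on
    the input matrix, then the zeroing is applied at once, so the outcome
    does not depend on any processing order.  Tags already present on the
    input are preserved (zeroed wins over weak).
    """
    params = params or ScoringParams()
    m = hm.matrix
    zero_row = [_line_decisions(m[i, :], params)[0] for i in range(m.shape[0])]
    zero_col = [_line_decisions(m[:, j], params)[0] for j in range(m.shape[1])]

    out = hm.copy()
    for i, zero in enumerate(zero_row):
        if zero:
            out.matrix[i, :] = 0.0
    for j, zero in enumerate(zero_col):
        if zero:
            out.matrix[:, j] = 0.0

    # the weak rule applies to the lines remaining unfiltered, so it is
    # evaluated on the zeroed matrix; this also makes the filter a fixed
    # point of itself (re-application changes nothing)
    def merge(prev: Tag, zero: bool, weak: bool) -> Tag:
        if zero or prev is Tag.ZEROED:
            return Tag.ZEROED
        if weak or prev is Tag.WEAK:
            return Tag.WEAK
        return Tag.NONE

    out.row_tags = [
        merge(hm.row_tags[i], z, _line_decisions(out.matrix[i, :], params)[1])
        for i, z in enumerate(zero_row)
    ]
    out.col_tags = [
        merge(hm.col_tags[j], z, _line_decisions(out.matrix[:, j], params)[1])
        for j, z in enumerate(zero_col)
    ]
    return out


def enhance_single_strong_probe(hm: ChimericHeatmap, params: ScoringParams | None = None) -> ChimericHeatmap:
    """Promote a lone outlier chimeric probe to the sentinel score.

    If the heatmap maximum exceeds the second-largest entry by at least the
    enhancement margin (0.8), the maximum cell is set to 6.0 — or to 3.0
    when its row or column carries the weak-half-binding tag.  At most one
    cell is modified; ties for the maximum leave the heatmap unchanged
    (their gap is zero).  Run after :func:`reduce_half_binders`; zeroed
    cells participate as 0 in the runner-up.
    """
    params = params or ScoringParams()
    m = hm.matrix
    if m.size < 2:
        return hm.copy()
    flat = m.ravel()
    order = np.argsort(flat, kind="stable")
    m1 = float(flat[order[-1]])
    m2 = float(flat[order[-2]])
    out = hm.copy()
    if m1 - m2 >= params.enhancement_margin:
        # first argmax in row-major order (unique here: a tie implies gap 0)
        i, j = np.unravel_index(int(np.argmax(m)), m.shape)
        weak = hm.row_tags[i] is Tag.WEAK or hm.col_tags[j] is Tag.WEAK
        out.matrix[i, j] = params.weak_adjust_value if weak else params.adjusted_to_max
    return out
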