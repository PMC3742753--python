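"""Breakpoint scoring and per-sample ranking of candidate fusions.

For a breakpoint (i, j) the fused transcript keeps exons 1..i of the 5'
partner A and exons j..n_B of the 3' partner B.  The four segments are

    A1 = exons 1..i of A        A2 = exons i+1..n_A of A
    B1 = exons 1..j-1 of B      B2 = exons j..n_B of B

and the fusion score combines the chimeric junction probe (capped at 3.0)
with the expression discontinuity |A2-A1| and |B2-B1| in the two partners
(each capped at 1.5), except that a heatmap cell carrying the enhancement
sentinel 6.0 scores 6.0 outright.  A cascade of guard branches scores 0.1
for degenerate or implausible profile shapes (empty B1; single-exon
segments that cannot support the observed imbalance direction).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    BreakpointScore,
    ChimericHeatmap,
    FusionCandidate,
    FusionScoreResult,
    IntensityTable,
    IntragenicProfile,
    ProbeAnnotation,
    ScoringParams,
    Tag,
    ValidationError,
)
from .preprocess import (
    NormalizationConfig,
    enhance_single_strong_probe,
    normalize_scores,
    reduce_half_binders,
    reference_probe_ids,
)
from .io import assemble_from_scores

__all__ = [
    "segment_means",
    "score_breakpoint",
    "score_fusion",
    "score_candidate",
    "score_sample",
    "rank_sample",
]


def segment_means(
    profile_a: IntragenicProfile, profile_b: IntragenicProfile, i: int, j: int
) -> Tuple[float, float, float, float, int, int, int, int]:
    """Segment means and lengths for breakpoint (i, j).

    Returns ``(a1_mean, a2_mean, b1_mean, b2_mean, len_a1, len_a2, len_b1,
    len_b2)``; the mean of an empty segment is 0.
    """
    na, nb = profile_a.n_exons, profile_b.n_exons
    if not (1 <= i <= na):
        raise ValidationError(f"exon index i={i} out of range 1..{na}")
    if not (1 <= j <= nb):
        raise ValidationError(f"exon index j={j} out of range 1..{nb}")
    a = profile_a.exon_scores
    b = profile_b.exon_scores

    def mean(seg: np.ndarray) -> float:
        return float(seg.mean()) if seg.size else 0.0

    return (
        mean(a[:i]),
        mean(a[i:]),
        mean(b[: j - 1]),
        mean(b[j - 1 :]),
        i,
        na - i,
        j - 1,
        nb - j + 1,
    )


def score_breakpoint(
    a1: float,
    a2: float,
    b1: float,
    b2: float,
    len_a1: int,
    len_a2: int,
    len_b1: int,
    len_b2: int,
    chimeric_value: float,
    params: ScoringParams | None = None,
    exon_a: int = 0,
    exon_b: int = 0,
) -> BreakpointScore:
    """Score one breakpoint from its segment means and chimeric probe value.

    The guard branches are evaluated in a fixed order with strict
    inequalities; equal means fall through to the scoring branch.  The
    enhancement sentinel is recognized by exact equality with
    ``adjusted_to_max`` — the enhancement step assigns that constant
    bit-exactly, so no tolerance is involved.
    """
    params = params or ScoringParams()
    break_a = 0.0
    break_b = 0.0
    if len_b1 == 0:
        score = params.degenerate_score
    elif ((a1 > a2 and b2 < b1) or (a1 < a2 and b2 > b1)) and len_a2 <= 1 and len_b2 <= 1:
        score = params.degenerate_score
    elif a1 < a2 and b2 > b1 and len_a1 <= 1 and len_b1 <= 1:
        score = params.degenerate_score
    elif (a1 > a2 and b1 < b2 and len_b2 <= 1) or (a1 < a2 and b1 > b2 and len_a2 <= 1):
        score = params.degenerate_score
    else:
        if chimeric_value == params.adjusted_to_max:  # enhancement sentinel
            score = chimeric_value
        else:
            break_a = min(abs(a2 - a1), params.max_break_score)
            break_b = min(abs(b2 - b1), params.max_break_score)
            score = min(chimeric_value, params.chimeric_cutoff) + break_a + break_b
            # never binds at the published constants (3.0 + 1.5 + 1.5 = 6.0)
            score = min(score, params.adjusted_to_max)
    return BreakpointScore(
        exon_a=exon_a,
        exon_b=exon_b,
        a1_mean=a1,
        a2_mean=a2,
        b1_mean=b1,
        b2_mean=b2,
        len_a1=len_a1,
        len_a2=len_a2,
        len_b1=len_b1,
        len_b2=len_b2,
        chimeric_value=chimeric_value,
        break_score_a=break_a,
        break_score_b=break_b,
        fusion_score=score,
    )


def _cell_tags(hm: ChimericHeatmap, i: int, j: int) -> Tuple[str, ...]:
    tags = []
    for axis, tag in (("row", hm.row_tags[i - 1]), ("col", hm.col_tags[j - 1])):
        if tag is not Tag.NONE:
            tags.append(f"{axis}:{tag.value}")
    return tuple(tags)


def score_fusion(
    hm: ChimericHeatmap,
    prof_a: IntragenicProfile,
    prof_b: IntragenicProfile,
    params: ScoringParams | None = None,
) -> FusionScoreResult:
    """Score every breakpoint of one (filtered, enhanced) heatmap.

    The candidate's score is the maximum over all (i, j); ties are broken by
    larger chimeric value, then by smaller (i, j) lexicographically.
    Returns an unranked result recording the winning breakpoint.
    """
    params = params or ScoringParams()
    na, nb = hm.matrix.shape
    best: Optional[BreakpointScore] = None
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            seg = segment_means(prof_a, prof_b, i, j)
            bp = score_breakpoint(*seg, float(hm.matrix[i - 1, j - 1]), params, exon_a=i, exon_b=j)
            if best is None or (bp.fusion_score, bp.chimeric_value) > (best.fusion_score, best.chimeric_value):
                best = bp
    assert best is not None
    return FusionScoreResult(
        fusion_id=hm.fusion_id,
        best_breakpoint=best,
        fusion_score=best.fusion_score,
        variant_a_id=hm.variant_a.variant_id,
        variant_b_id=hm.variant_b.variant_id,
        tags=_cell_tags(hm, best.exon_a, best.exon_b),
    )


def score_candidate(
    candidate: FusionCandidate,
    scores: Dict[str, float],
    annotations: Sequence[ProbeAnnotation],
    params: ScoringParams | None = None,
    halfbinder_filter: bool = True,
    enhancement: bool = True,
) -> FusionScoreResult:
    """Assemble, filter, enhance and score one candidate.

    With several transcript-variant pairs, each pair is scored on its own
    heatmap and the candidate takes the maximum (ties: larger chimeric
    value, then lexicographic pair ids).
    """
    params = params or ScoringParams()
    best: Optional[FusionScoreResult] = None
    for pair in candidate.variant_pairs:
        hm, prof_a, prof_b = assemble_from_scores(scores, annotations, candidate, pair)
        if halfbinder_filter:
            hm = reduce_half_binders(hm, params)
        if enhancement:
            hm = enhance_single_strong_probe(hm, params)
        res = score_fusion(hm, prof_a, prof_b, params)
        if best is None:
            best = res
            continue
        key_res = (res.fusion_score, res.best_breakpoint.chimeric_value)
        key_best = (best.fusion_score, best.best_breakpoint.chimeric_value)
        if key_res > key_best or (
            key_res == key_best
            and (res.variant_a_id, res.variant_b_id) < (best.variant_a_id, best.variant_b_id)
        ):
            best = res
    assert best is not None
    return best


def rank_sample(results: Sequence[FusionScoreResult]) -> List[FusionScoreResult]:
    """Assign ranks 1..K by descending fusion score.

    Ties are broken by the best breakpoint's chimeric value (descending),
    then by fusion_id (lexicographic), making the ordering deterministic.
    """
    ordered = sorted(
        results,
        key=lambda r: (-r.fusion_score, -r.best_breakpoint.chimeric_value, r.fusion_id),
    )
    for k, r in enumerate(ordered, start=1):
        r.rank = k
    return ordered


def score_sample(
    sample: IntensityTable,
    annotations: Sequence[ProbeAnnotation],
    panel: Sequence[FusionCandidate],
    params: ScoringParams | None = None,
    norm_config: NormalizationConfig | None = None,
    halfbinder_filter: bool = True,
    enhancement: bool = True,
) -> List[FusionScoreResult]:
    """Run the full per-sample pipeline and return the ranked panel."""
    scores = normalize_scores(sample, norm_config, reference_probe_ids(annotations, norm_config))
    results = [
        score_candidate(c, scores, annotations, params, halfbinder_filter, enhancement) for c in panel
    ]
    return rank_sample(results)
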