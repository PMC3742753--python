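"""Readers/writers for panels, probe annotations, intensities and reports.

All tabular files are UTF-8, tab-delimited TSV with a header row, ``'.'``
decimal separator, and ``'#'`` comment lines.  File layouts:

panel TSV
    ``fusion_id  gene_a  variant_a  n_exons_a  gene_b  variant_b  n_exons_b``
    One row per (variant_a, variant_b) pair; rows sharing a fusion_id
    aggregate into one candidate with several variant pairs.

probe annotation TSV
    ``probe_id  fusion_id  probe_type  gene  variant_id  exon_a  exon_b``
    Empty exon field = absent.  Chimeric rows encode the partner pair as
    ``GENEA::GENEB`` / ``va::vb`` in the gene/variant columns.

intensity TSV
    ``probe_id  intensity``

report TSV
    ``rank  fusion_id  fusion_score  exon_a  exon_b  chimeric_value
    break_score_a  break_score_b  tags``
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    AssemblyError,
    ChimericHeatmap,
    FormatError,
    FusionCandidate,
    IntensityTable,
    IntragenicProfile,
    MissingProbeError,
    PAIR_SEP,
    ProbeAnnotation,
    ProbeType,
    TranscriptVariant,
    ValidationError,
)
from .preprocess import NormalizationConfig, normalize_scores, reference_probe_ids

__all__ = [
    "load_panel",
    "write_panel",
    "load_annotations",
    "write_annotations",
    "load_intensities",
    "write_intensities",
    "assemble",
    "assemble_from_scores",
    "write_report",
]

PANEL_COLUMNS = ["fusion_id", "gene_a", "variant_a", "n_exons_a", "gene_b", "variant_b", "n_exons_b"]
ANNOTATION_COLUMNS = ["probe_id", "fusion_id", "probe_type", "gene", "variant_id", "exon_a", "exon_b"]
REPORT_COLUMNS = [
    "rank",
    "fusion_id",
    "fusion_score",
    "exon_a",
    "exon_b",
    "chimeric_value",
    "break_score_a",
    "break_score_b",
    "tags",
]


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed file, not a domain error
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def load_panel(path) -> List[FusionCandidate]:
    """Read a fusion panel TSV into validated candidates.

    Rows sharing a ``fusion_id`` contribute variant pairs to the same
    candidate; an exactly repeated (fusion_id, variant_a, variant_b) triple
    is an error.
    """
    df = _read_tsv(path, PANEL_COLUMNS)
    order: List[str] = []
    pairs: Dict[str, List[Tuple[TranscriptVariant, TranscriptVariant]]] = {}
    seen = set()
    for row in df.itertuples(index=False):
        fid = row.fusion_id
        key = (fid, row.variant_a, row.variant_b)
        if key in seen:
            raise FormatError(f"{path}: duplicate panel entry {key}")
        seen.add(key)
        try:
            na, nb = int(row.n_exons_a), int(row.n_exons_b)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer exon count for {fid}") from exc
        va = TranscriptVariant(row.gene_a, row.variant_a, na)
        vb = TranscriptVariant(row.gene_b, row.variant_b, nb)
        if fid not in pairs:
            order.append(fid)
            pairs[fid] = []
        pairs[fid].append((va, vb))
    return [FusionCandidate(fid, tuple(pairs[fid])) for fid in order]


def write_panel(candidates: Iterable[FusionCandidate], path) -> None:
    rows = []
    for c in candidates:
        for va, vb in c.variant_pairs:
            rows.append(
                {
                    "fusion_id": c.fusion_id,
                    "gene_a": va.gene_symbol,
                    "variant_a": va.variant_id,
                    "n_exons_a": va.n_exons,
                    "gene_b": vb.gene_symbol,
                    "variant_b": vb.variant_id,
                    "n_exons_b": vb.n_exons,
                }
            )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def load_annotations(path) -> List[ProbeAnnotation]:
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    out: List[ProbeAnnotation] = []
    seen = set()
    for k, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ptype = ProbeType(row.probe_type)
        except ValueError as exc:
            raise FormatError(f"{path}:{k}: unknown probe_type {row.probe_type!r}") from exc
        ea = int(row.exon_a) if row.exon_a != "" else None
        eb = int(row.exon_b) if row.exon_b != "" else None
        ann = ProbeAnnotation(row.probe_id, row.fusion_id, ptype, row.gene, row.variant_id, ea, eb)
        key = (ann.fusion_id, ann.probe_type, ann.variant_id, ann.exon_a, ann.exon_b)
        if key in seen:
            raise ValidationError(f"{path}:{k}: duplicate annotation {key}")
        seen.add(key)
        out.append(ann)
    return out


def write_annotations(annotations: Iterable[ProbeAnnotation], path) -> None:
    rows = [
        {
            "probe_id": a.probe_id,
            "fusion_id": a.fusion_id,
            "probe_type": a.probe_type.value,
            "gene": a.gene,
            "variant_id": a.variant_id,
            "exon_a": "" if a.exon_a is None else a.exon_a,
            "exon_b": "" if a.exon_b is None else a.exon_b,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def load_intensities(path, annotations: Sequence[ProbeAnnotation], sample_id: str | None = None) -> IntensityTable:
    """Read a two-column intensity TSV, validated against the annotation.

    Every annotated probe must be present (missing probes are an error — no
    imputation), and intensities must be non-negative.
    """
    path = Path(path)
    df = _read_tsv(path, ["probe_id", "intensity"])
    values: Dict[str, float] = {}
    for k, row in enumerate(df.itertuples(index=False), start=2):
        try:
            v = float(row.intensity)
        except ValueError as exc:
            raise FormatError(f"{path}:{k}: non-numeric intensity {row.intensity!r}") from exc
        if v < 0:
            raise ValidationError(f"{path}:{k}: negative intensity {v} for probe {row.probe_id}")
        values[row.probe_id] = v
    needed = {a.probe_id for a in annotations}
    absent = needed - values.keys()
    if absent:
        raise MissingProbeError(sorted(absent))
    return IntensityTable(sample_id or path.stem, values)


def write_intensities(table: IntensityTable, path) -> None:
    pd.DataFrame(
        {"probe_id": list(table.values.keys()), "intensity": list(table.values.values())}
    ).to_csv(path, sep="\t", index=False)


def _pair_key(fusion_id: str, va: TranscriptVariant, vb: TranscriptVariant) -> Tuple[str, str]:
    return (fusion_id, f"{va.variant_id}{PAIR_SEP}{vb.variant_id}")


def assemble_from_scores(
    scores: Dict[str, float],
    annotations: Sequence[ProbeAnnotation],
    candidate: FusionCandidate,
    pair: Tuple[TranscriptVariant, TranscriptVariant] | None = None,
) -> Tuple[ChimericHeatmap, IntragenicProfile, IntragenicProfile]:
    """Build the heatmap and both partner profiles from normalized scores.

    ``pair`` selects the (variant_A, variant_B) pair; it may be omitted for
    single-pair candidates.  Every exon-exon combination and every exon of
    both variants must be annotated and scored, exactly once.
    """
    if pair is None:
        if len(candidate.variant_pairs) != 1:
            raise AssemblyError(f"{candidate.fusion_id}: candidate has several variant pairs; specify one")
        pair = candidate.variant_pairs[0]
    va, vb = pair
    want_chim = _pair_key(candidate.fusion_id, va, vb)[1]

    hm = np.full((va.n_exons, vb.n_exons), np.nan)
    prof_a = np.full(va.n_exons, np.nan)
    prof_b = np.full(vb.n_exons, np.nan)
    for a in annotations:
        if a.fusion_id != candidate.fusion_id:
            continue
        if a.probe_type is ProbeType.CHIMERIC:
            if a.variant_id != want_chim:
                continue
            i, j = a.exon_a, a.exon_b
            if not (1 <= i <= va.n_exons and 1 <= j <= vb.n_exons):
                raise AssemblyError(f"{candidate.fusion_id}: chimeric probe {a.probe_id} exon out of range")
            if not np.isnan(hm[i - 1, j - 1]):
                raise AssemblyError(f"{candidate.fusion_id}: duplicate chimeric probe at ({i}, {j})")
            hm[i - 1, j - 1] = _score_of(scores, a.probe_id)
        else:
            if a.gene == va.gene_symbol and a.variant_id == va.variant_id and a.exon_a is not None:
                prof_a[a.exon_a - 1] = _score_of(scores, a.probe_id)
            elif a.gene == vb.gene_symbol and a.variant_id == vb.variant_id and a.exon_b is not None:
                prof_b[a.exon_b - 1] = _score_of(scores, a.probe_id)
    for name, arr in (("heatmap", hm), ("profile A", prof_a), ("profile B", prof_b)):
        if np.isnan(arr).any():
            n_missing = int(np.isnan(arr).sum())
            raise AssemblyError(
                f"{candidate.fusion_id} ({va.variant_id}, {vb.variant_id}): {n_missing} missing {name} probe(s)"
            )
    return (
        ChimericHeatmap(candidate.fusion_id, va, vb, hm),
        IntragenicProfile(va.gene_symbol, va.variant_id, prof_a),
        IntragenicProfile(vb.gene_symbol, vb.variant_id, prof_b),
    )


def _score_of(scores: Dict[str, float], probe_id: str) -> float:
    try:
        return scores[probe_id]
    except KeyError as exc:
        raise MissingProbeError([probe_id]) from exc


def assemble(
    sample: IntensityTable,
    annotations: Sequence[ProbeAnnotation],
    candidate: FusionCandidate,
    pair: Tuple[TranscriptVariant, TranscriptVariant] | None = None,
    norm_config: NormalizationConfig | None = None,
) -> Tuple[ChimericHeatmap, IntragenicProfile, IntragenicProfile]:
    """Normalize a raw sample and assemble one candidate's evidence."""
    scores = normalize_scores(sample, norm_config, reference_probe_ids(annotations, norm_config))
    return assemble_from_scores(scores, annotations, candidate, pair)


def write_report(results: Sequence, path) -> None:
    """Write the ranked per-candidate report; byte-deterministic for equal input."""
    rows = []
    for r in results:
        bp = r.best_breakpoint
        rows.append(
            {
                "rank": r.rank,
                "fusion_id": r.fusion_id,
                "fusion_score": bp.fusion_score,
                "exon_a": bp.exon_a,
                "exon_b": bp.exon_b,
                "chimeric_value": bp.chimeric_value,
                "break_score_a": bp.break_score_a,
                "break_score_b": bp.break_score_b,
                "tags": ";".join(r.tags),
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
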