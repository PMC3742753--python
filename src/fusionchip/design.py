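"""Probe target-sequence design for a fusion candidate panel.

For each candidate the designer emits one intragenic probe per exon of both
partners (centered in the exon) and one chimeric junction probe per
exon-exon combination, built by concatenating the last ``arm_length`` bases
of exon i of the 5' partner with the first ``arm_length`` bases of exon j
of the 3' partner.  Probes are written on the sense (mRNA) strand;
reverse-complementation for synthesis is downstream of this tool.

Exon FASTA records are named ``gene|variant|exon_index`` (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import DesignError, FusionCandidate, ProbeAnnotation, ProbeType, PAIR_SEP, ValidationError
from .panels import chimeric_probe_id, intragenic_probe_id

__all__ = ["DesignConfig", "design_probes", "read_exon_fasta", "write_probe_fasta"]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class DesignConfig:
    """Probe geometry.

    ``arm_length`` bases are taken from each side of the junction, so a
    chimeric probe is at most ``2 * arm_length`` long; an exon shorter than
    an arm contributes its full sequence (no padding).
    """

    arm_length: int = 30
    intragenic_probe_length: int = 60

    def __post_init__(self):
        if self.arm_length < 10:
            raise ValidationError("arm_length must be >= 10")
        if self.intragenic_probe_length < 1:
            raise ValidationError("intragenic_probe_length must be >= 1")

    @property
    def probe_length(self) -> int:
        return 2 * self.arm_length


def read_exon_fasta(path) -> Dict[Tuple[str, str, int], str]:
    """Read exon sequences keyed by (gene, variant, exon_index)."""
    out: Dict[Tuple[str, str, int], str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise DesignError(f"{path}: record {rec.id!r} is not gene|variant|exon_index")
        gene, variant, exon = parts
        try:
            k = int(exon)
        except ValueError as exc:
            raise DesignError(f"{path}: record {rec.id!r} has non-integer exon index") from exc
        seq = str(rec.seq).upper()
        if not seq or not set(seq) <= _ALPHABET:
            raise DesignError(f"{path}: record {rec.id!r} has a non-ACGTN sequence")
        out[(gene, variant, k)] = seq
    return out


def _exon_seq(exons: Dict[Tuple[str, str, int], str], gene: str, variant: str, k: int) -> str:
    try:
        seq = exons[(gene, variant, k)]
    except KeyError as exc:
        raise DesignError(f"missing exon record {gene}|{variant}|{k}") from exc
    if set(seq) == {"N"}:
        raise DesignError(f"exon {gene}|{variant}|{k} contains only N")
    return seq


def _centered(seq: str, length: int) -> str:
    if len(seq) <= length:
        return seq
    start = (len(seq) - length) // 2
    return seq[start : start + length]


def design_probes(
    exons_a: Dict[Tuple[str, str, int], str],
    exons_b: Dict[Tuple[str, str, int], str],
    candidate: FusionCandidate,
    config: DesignConfig | None = None,
) -> Tuple[List[SeqRecord], List[ProbeAnnotation]]:
    """Design all probes for one candidate (all its variant pairs).

    Returns FASTA records and annotation rows that exactly mirror each
    other; descriptions record the realized arm lengths for short exons.
    """
    config = config or DesignConfig()
    records: List[SeqRecord] = []
    annotations: List[ProbeAnnotation] = []
    emitted = set()
    for va, vb in candidate.variant_pairs:
        pair_gene = f"{va.gene_symbol}{PAIR_SEP}{vb.gene_symbol}"
        pair_var = f"{va.variant_id}{PAIR_SEP}{vb.variant_id}"
        for variant, exons, side in ((va, exons_a, "a"), (vb, exons_b, "b")):
            for k in range(1, variant.n_exons + 1):
                pid = intragenic_probe_id(variant.gene_symbol, variant.variant_id, k)
                seq = _centered(
                    _exon_seq(exons, variant.gene_symbol, variant.variant_id, k),
                    config.intragenic_probe_length,
                )
                if pid not in emitted:  # shared across candidates/partner roles
                    emitted.add(pid)
                    records.append(SeqRecord(Seq(seq), id=pid, description=f"intragenic len={len(seq)}"))
                annotations.append(
                    ProbeAnnotation(
                        pid,
                        candidate.fusion_id,
                        ProbeType.INTRAGENIC,
                        variant.gene_symbol,
                        variant.variant_id,
                        exon_a=k if side == "a" else None,
                        exon_b=k if side == "b" else None,
                    )
                )
        for i in range(1, va.n_exons + 1):
            arm_a = _exon_seq(exons_a, va.gene_symbol, va.variant_id, i)[-config.arm_length :]
            for j in range(1, vb.n_exons + 1):
                arm_b = _exon_seq(exons_b, vb.gene_symbol, vb.variant_id, j)[: config.arm_length]
                pid = chimeric_probe_id(va, vb, i, j)
                records.append(
                    SeqRecord(
                        Seq(arm_a + arm_b),
                        id=pid,
                        description=f"chimeric arms={len(arm_a)}+{len(arm_b)}",
                    )
                )
                annotations.append(
                    ProbeAnnotation(
                        pid,
                        candidate.fusion_id,
                        ProbeType.CHIMERIC,
                        pair_gene,
                        pair_var,
                        exon_a=i,
                        exon_b=j,
                    )
                )
    return records, annotations


def write_probe_fasta(records: Sequence[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")
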