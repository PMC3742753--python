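"""Built-in fusion panels and programmatic probe-annotation construction.

The sarcoma panel lists 38 candidate fusion genes drawn from the recurrent,
diagnostically used sarcoma fusions (Ewing sarcoma EWSR1 family, synovial
sarcoma SS18-SSX, myxoid liposarcoma FUS/EWSR1-DDIT3, alveolar
rhabdomyosarcoma PAX3/7-FOXO1, and so on).  The transcript models are
synthetic: one variant per gene with a plausible-magnitude exon count.
They define the scoring universe for simulation and benchmarking, not an
annotation of any physical array.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

from .model import (
    FusionCandidate,
    PAIR_SEP,
    ProbeAnnotation,
    ProbeType,
    TranscriptVariant,
)

__all__ = ["sarcoma_panel", "toy_panel", "build_annotations", "EXON_COUNTS", "SARCOMA_FUSIONS"]

# Synthetic exon counts per partner gene (order-of-magnitude realistic,
# capped to keep the probe universe desk-scale).
EXON_COUNTS: Dict[str, int] = {
    "EWSR1": 16,
    "FLI1": 9,
    "ERG": 11,
    "ETV1": 13,
    "ETV4": 13,
    "FEV": 3,
    "PATZ1": 6,
    "NFATC2": 10,
    "SMARCA5": 16,
    "SP3": 7,
    "NR4A3": 8,
    "TAF15": 16,
    "TCF12": 16,
    "TFG": 8,
    "ATF1": 7,
    "CREB1": 8,
    "DDIT3": 4,
    "FUS": 15,
    "CREB3L2": 12,
    "CREB3L1": 12,
    "SS18": 11,
    "SSX1": 9,
    "SSX2": 9,
    "SSX4": 9,
    "SS18L1": 11,
    "PAX3": 9,
    "PAX7": 9,
    "FOXO1": 3,
    "NCOA1": 16,
    "COL1A1": 16,
    "PDGFB": 7,
    "ETV6": 8,
    "NTRK3": 16,
    "ASPSCR1": 13,
    "TFE3": 10,
    "JAZF1": 5,
    "SUZ12": 16,
    "PHF1": 15,
    "EPC1": 14,
    "POU5F1": 5,
    "HEY1": 5,
    "NCOA2": 16,
    "TPM3": 13,
    "ALK": 16,
}

# 38 candidate sarcoma fusions (5' partner, 3' partner).
SARCOMA_FUSIONS: Tuple[Tuple[str, str], ...] = (
    ("EWSR1", "FLI1"),
    ("EWSR1", "ERG"),
    ("EWSR1", "ETV1"),
    ("EWSR1", "ETV4"),
    ("EWSR1", "FEV"),
    ("EWSR1", "PATZ1"),
    ("EWSR1", "NFATC2"),
    ("EWSR1", "SMARCA5"),
    ("EWSR1", "SP3"),
    ("EWSR1", "NR4A3"),
    ("TAF15", "NR4A3"),
    ("TCF12", "NR4A3"),
    ("TFG", "NR4A3"),
    ("EWSR1", "ATF1"),
    ("EWSR1", "CREB1"),
    ("EWSR1", "DDIT3"),
    ("FUS", "DDIT3"),
    ("FUS", "ATF1"),
    ("FUS", "CREB3L2"),
    ("FUS", "CREB3L1"),
    ("EWSR1", "CREB3L1"),
    ("SS18", "SSX1"),
    ("SS18", "SSX2"),
    ("SS18", "SSX4"),
    ("SS18L1", "SSX1"),
    ("PAX3", "FOXO1"),
    ("PAX7", "FOXO1"),
    ("PAX3", "NCOA1"),
    ("COL1A1", "PDGFB"),
    ("ETV6", "NTRK3"),
    ("ASPSCR1", "TFE3"),
    ("JAZF1", "SUZ12"),
    ("JAZF1", "PHF1"),
    ("EPC1", "PHF1"),
    ("FUS", "ERG"),
    ("EWSR1", "POU5F1"),
    ("HEY1", "NCOA2"),
    ("TPM3", "ALK"),
)


def _variant(gene: str, n_exons: int | None = None, variant_id: str = "v1") -> TranscriptVariant:
    return TranscriptVariant(gene, variant_id, n_exons if n_exons is not None else EXON_COUNTS[gene])


def sarcoma_panel() -> List[FusionCandidate]:
    """The built-in 38-candidate sarcoma fusion panel (one variant pair each)."""
    return [
        FusionCandidate(f"{ga}-{gb}", ((_variant(ga), _variant(gb)),)) for ga, gb in SARCOMA_FUSIONS
    ]


def toy_panel() -> List[FusionCandidate]:
    """A tiny 3-candidate panel for examples and fast tests."""
    return [
        FusionCandidate("AAA-BBB", ((_variant("AAA", 4), _variant("BBB", 5)),)),
        FusionCandidate("CCC-DDD", ((_variant("CCC", 3), _variant("DDD", 4)),)),
        FusionCandidate("AAA-DDD", ((_variant("AAA", 4), _variant("DDD", 4)),)),
    ]


def intragenic_probe_id(gene: str, variant_id: str, exon: int) -> str:
    return f"g|{gene}.{variant_id}.e{exon}"


def chimeric_probe_id(va: TranscriptVariant, vb: TranscriptVariant, i: int, j: int) -> str:
    return f"c|{va.key}.e{i}|{vb.key}.e{j}"


def build_annotations(panel: Sequence[FusionCandidate]) -> List[ProbeAnnotation]:
    """Annotation rows covering every chimeric combination and every exon.

    Intragenic probes are physical per (gene, variant, exon) and shared
    between candidates referencing the same partner gene; they get one
    annotation row per candidate (same probe_id).  Chimeric probes are
    unique per variant pair.
    """
    rows: List[ProbeAnnotation] = []
    for c in panel:
        for va, vb in c.variant_pairs:
            pair_gene = f"{va.gene_symbol}{PAIR_SEP}{vb.gene_symbol}"
            pair_var = f"{va.variant_id}{PAIR_SEP}{vb.variant_id}"
            for i in range(1, va.n_exons + 1):
                for j in range(1, vb.n_exons + 1):
                    rows.append(
                        ProbeAnnotation(
                            chimeric_probe_id(va, vb, i, j),
                            c.fusion_id,
                            ProbeType.CHIMERIC,
                            pair_gene,
                            pair_var,
                            exon_a=i,
                            exon_b=j,
                        )
                    )
            for i in range(1, va.n_exons + 1):
                rows.append(
                    ProbeAnnotation(
                        intragenic_probe_id(va.gene_symbol, va.variant_id, i),
                        c.fusion_id,
                        ProbeType.INTRAGENIC,
                        va.gene_symbol,
                        va.variant_id,
                        exon_a=i,
                    )
                )
            for j in range(1, vb.n_exons + 1):
                rows.append(
                    ProbeAnnotation(
                        intragenic_probe_id(vb.gene_symbol, vb.variant_id, j),
                        c.fusion_id,
                        ProbeType.INTRAGENIC,
                        vb.gene_symbol,
                        vb.variant_id,
                        exon_b=j,
                    )
                )
    return rows
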