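import numpy as np
import pytest

from fusionchip import (
    ChimericHeatmap,
    IntragenicProfile,
    TranscriptVariant,
    build_annotations,
    toy_panel,
)


def make_heatmap(matrix, fusion_id="GA-GB") -> ChimericHeatmap:
    """Wrap a plain matrix in a heatmap with ad-hoc variants of fitting size."""
    m = np.asarray(matrix, dtype=float)
    va = TranscriptVariant("GA", "v1", m.shape[0])
    vb = TranscriptVariant("GB", "v1", m.shape[1])
    return ChimericHeatmap(fusion_id, va, vb, m)


def make_profile(scores, gene="GA") -> IntragenicProfile:
    return IntragenicProfile(gene, "v1", np.asarray(scores, dtype=float))


@pytest.fixture(scope="session")
def toy():
    panel = toy_panel()
    return panel, build_annotations(panel)


def random_exons(rng, gene, variant, n_exons, min_len=40, max_len=120):
    """(key -> sequence) exon dict with random ACGT sequences."""
    out = {}
    for k in range(1, n_exons + 1):
        L = int(rng.integers(min_len, max_len + 1))
        out[(gene, variant, k)] = "".join(rng.choice(list("ACGT"), size=L))
    return out
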