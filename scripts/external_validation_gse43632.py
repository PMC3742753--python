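#!/usr/bin/env python
"""OPTIONAL external validation against the original sarcoma arrays.

This script is NOT part of the test suite or the acceptance run and nothing
in the package depends on it.  The original study's raw and processed data
are deposited in the Gene Expression Omnibus under accession GSE43632; the
array-level probe annotation and the normalization of the original platform
come from the authors' earlier array publication and are not redistributed
here.  To attempt the comparison you must therefore prepare, yourself:

  1. a panel TSV and probe-annotation TSV describing the 38 sarcoma
     candidates on the physical array (layouts: see fusionchip.io),
  2. one intensity TSV per sample extracted from the GEO record, and
  3. a two-column TSV `sample_id  expected_fusion` with the RT-PCR/
     karyotyping ground truth of the samples you exported.

Given those, the script runs the standard scoring pipeline and prints each
sample's rank of the expected fusion plus top-1 / top-3 tallies.

Usage:
    python scripts/external_validation_gse43632.py \
        --panel panel.tsv --probes probes.tsv --truth truth.tsv \
        sample1.tsv sample2.tsv ...
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

from fusionchip import load_annotations, load_intensities, load_panel, score_sample


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", required=True)
    ap.add_argument("--probes", required=True)
    ap.add_argument("--truth", required=True)
    ap.add_argument("samples", nargs="+", help="one intensity TSV per sample")
    args = ap.parse_args()

    panel = load_panel(args.panel)
    annotations = load_annotations(args.probes)
    truth = dict(
        pd.read_csv(args.truth, sep="\t", dtype=str).itertuples(index=False, name=None)
    )

    top1 = top3 = n = 0
    print("sample_id\texpected_fusion\trank\ttop_hit\ttop_score")
    for path in args.samples:
        sample = load_intensities(path, annotations)
        expected = truth.get(sample.sample_id)
        if expected is None:
            print(f"{sample.sample_id}\t?\t-\t-\t-", file=sys.stderr)
            continue
        ranked = score_sample(sample, annotations, panel)
        rank = next((r.rank for r in ranked if r.fusion_id == expected), None)
        n += 1
        if rank == 1:
            top1 += 1
        if rank is not None and rank <= 3:
            top3 += 1
        print(f"{sample.sample_id}\t{expected}\t{rank}\t{ranked[0].fusion_id}\t{ranked[0].fusion_score:.3f}")
    if n:
        print(f"\ntop-1: {top1}/{n}\ttop-3: {top3}/{n}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
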