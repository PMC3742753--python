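# Methods

This note documents the models, parameter choices and numerical decisions
behind `fusionchip`, in the order the pipeline applies them.

## Data model

A candidate fusion A→B is probed in the A₁+B₂ constellation only: exons
`1..i` of the 5′ partner joined to exons `j..n_B` of the 3′ partner.  All
exon indices are 1-based, so the cell (13, 3) of a heatmap is the probe
joining exon 13 of A to exon 3 of B.  A candidate may carry several
(variant_A, variant_B) transcript pairs — one heatmap each — and its score
is the maximum over pairs; this is the permissive choice for a panel whose
variant structure is uncertain, and the report names the winning pair.
Intragenic profiles are computed per transcript variant, not pooled across
variants sharing exons.

## Normalization

Raw fluorescence is mapped to scores as `log2(intensity + pseudocount)`
minus a median center, with negatives floored at 0 (configurable:
`log2_only`, `none`; pseudocount default 1.0).  On this scale the printed
constants are meaningful: 3.0 ≈ 8-fold over baseline, the strongest
chimeric evidence the composite score will accept.

The centering reference is the **intragenic probe set**, not the whole
array.  Half-binding is an artifact specific to chimeric junction probes:
one arm binds an abundant wild-type cDNA by itself.  On a badly striped
array a large fraction of chimeric probes is elevated, so an all-probe
median drifts upward and the zero-floor then erases the intragenic
profiles — exactly the evidence the break terms need.  The intragenic
probes cannot be struck by half-binding and form a stable baseline; the
behaviour is configurable back to `reference: all`.

The floor at 0 keeps unexpressed probes from contributing negative
chimeric scores or spurious segment-mean differences; its consequence is
that the fusion score is bounded in [0, 6] for all pipeline-produced
inputs.

## Half-binder reduction

For every row and column of a heatmap, two zeroing triggers are evaluated:
(1) at least 25% of the line's probes score at or above 70% of the line
maximum, or (2) at least three probes reach the chimeric cutoff 3.0.  A
triggered line is set to 0 entirely and tagged `zeroed`.  Among the
surviving lines, any with at least 25% of probes at or above 50% of the
maximum is tagged `weak_half_binding`, which later caps the enhancement.

Numerical decisions:

* **Both relative triggers additionally require two qualifying probes.**
  The line maximum always qualifies against itself, so in any line of four
  or fewer probes a lone strong probe would otherwise zero (or weak-tag)
  its own line — and a lone strong probe is precisely the true-positive
  signature the enhancement step exists to protect.  The same floor is
  applied to the weak rule for the same reason.
* **Zeroing decisions are taken simultaneously on the input matrix**, then
  applied at once.  This is the only order-invariant reading: permuting
  rows/columns commutes with the filter (property-tested).
* **The weak tag is evaluated on the post-zeroing matrix**: the rule
  concerns the lines remaining unfiltered, and this makes the tagging
  stable under re-application.
* **The filter is one-pass and not idempotent in general.**  Because the
  triggers are relative to the line maximum, they are scale-free: after
  flooring, near-zero noise lines qualify as (harmless) stripes, and
  zeroing them changes other lines' maxima, so a second application could
  zero further lines.  The pipeline applies the filter exactly once; what
  is guaranteed and tested is monotonicity — re-application only ever
  decreases entries and never removes a tag.  A line whose maximum is 0 is
  never triggered, so all-zero heatmaps pass through untouched.

## Single-strong-probe enhancement

After filtering, let m₁ be the heatmap maximum and m₂ the largest other
entry (zeroed cells participate as 0).  If m₁ − m₂ ≥ 0.8, the maximum cell
is set to exactly 6.0, or to 3.0 when its row or column carries the weak
tag.  At most one cell changes, and only the argmax cell; tied maxima have
gap 0 and are never enhanced.  The assignment is bit-exact, because the
scorer recognizes the sentinel by exact equality — a cell that happens to
score 6.0 on its own is indistinguishable by design, and a weak-capped
cell (3.0) is *not* a sentinel: it flows through the normal branch, where
the chimeric cutoff (also 3.0) caps it identically.

## Breakpoint score

Segments: A₁ = exons 1..i, A₂ = i+1..n_A, B₁ = 1..j−1, B₂ = j..n_B; means
are arithmetic means of normalized exon scores, and an empty segment has
mean 0 (the post-normalization noise level; most empty-segment cases are
intercepted by the length guards anyway).  The guard branches are
evaluated in fixed order with strict inequalities — equal means fall
through to the scoring branch:

1. empty B₁ → 0.1 (the junction would retain no 5′ exon of B);
2. imbalance in either direction resting on single-exon A₂ and B₂ → 0.1;
3. anti-fusion pattern (A rising, B rising) resting on single-exon leading
   segments → 0.1;
4. a single-exon downstream segment carrying the whole imbalance → 0.1;
5. otherwise: the sentinel scores itself, else
   `min(chimeric, 3.0) + min(|Ā₂−Ā₁|, 1.5) + min(|B̄₂−B̄₁|, 1.5)`, finally
   clamped at 6.0 (the clamp never binds at the default constants; it
   enforces the documented supremum under user-overridden parameters).

Branch 2's first clause penalizes a profile where A looks fused but B is
inverted; it is transcribed as printed, not rationalized.  The production
scorer is checked against an independent, literal transcription of the
branch structure on 10⁵ randomized inputs spanning every branch.

Per candidate, the score is maximized over all (i, j); ties prefer larger
chimeric value, then smaller (i, j) lexicographically.  Per sample,
candidates are ranked by descending score, ties broken by chimeric value
then fusion id, giving ranks 1..K deterministically.

## Synthetic-data generator

Intensities are drawn as `2^(baseline + effects + N(0, sd))` per probe —
lognormal noise, the standard single-channel microarray model.  Defaults:
baseline 8.0 log2 units, noise SD 0.3, chimeric boost +5.0 at the true
breakpoint cell, expression shift +2.0 on the retained exons (5′ of A, 3′
of B), half-binder strike probability 0.05 per heatmap row/column at +4.0.
The wild-type allele keeps all exons of both partners at baseline, so a
fused sample shows a *shift*, not an on/off profile.  Breakpoints with
j = 1 are never injected (the scorer defines them as degenerate).  Cluster
mode spreads the boost over a 2×2 block (primary cell at full boost,
in-bounds neighbours 1.0 log2 lower), imitating co-expressed transcript
variants.  Everything derives from the single seed; cohorts derive
per-sample seeds from it deterministically.

What the generator does **not** emulate: spatial array effects, dye bias,
probe-sequence affinity differences, RNA degradation, partner-promiscuity
correlations between candidates, and cross-hybridization beyond the
row/column striping model.  Passing tests therefore demonstrate the
algorithmic behaviour of the pipeline under its own signal model, not
clinical performance on physical arrays.

The built-in panel lists 38 recurrent sarcoma fusions with one synthetic
transcript model per gene (plausible-magnitude exon counts, capped at 16
to keep the probe universe around 5,200 probes).  It defines the scoring
universe for simulation; it does not annotate any physical array.

## Probe design

Chimeric probes concatenate the last `arm_length` (default 30) bases of
exon i of A with the first `arm_length` bases of exon j of B; intragenic
probes are centered in their exon (default 60 nt).  Exons shorter than an
arm contribute their full sequence — truncation preserves junction
specificity, and the FASTA description records the realized arm lengths.
Probes are written sense-strand; no melting-temperature or uniqueness
screening is performed (a config hook is left for a future filter).

## Ablation experiments

Two experiments mirror the role of the artifact steps:

* **Filter ablation** runs fusion-negative cohorts at strike probability
  0.5 with enhancement disabled in both arms, so only the factor under
  test varies.  A false-positive call is a wrong top hit scoring at or
  above the chimeric cutoff — i.e. carrying what looks like genuine
  junction evidence.  Without the filter every striped sample produces
  such a call; with it, on the same seeds, strictly fewer do.
* **Enhancement ablation** uses a noise-free fixture: a lone chimeric
  outlier (+2.2) with weak concordant shifts (+0.4) for the true fusion,
  and a decoy sharing the 5′ partner with two near-tied chimeric cells
  (+1.5/+1.4, hence no lone outlier) plus a stronger 3′ discontinuity
  (+1.2).  Without enhancement the decoy wins 3.1 to 3.0; with it the
  true fusion's outlier is promoted to 6.0 and ranks first.

Problem sizes used throughout the test and acceptance workloads — 38
candidates, ~5,200 probes, cohorts of 8–15 samples, 10⁴–10⁵ scorer
fuzz inputs — were chosen as the smallest sizes at which every behaviour
of interest (striping, rescue, rank recovery) is exercised with margin.

## Known limitations

* The exact membership of the original 38-fusion sarcoma panel is not
  redistributed; the built-in panel is a best-effort reconstruction and
  the transcript models are synthetic.
* Scores are ranks, not calibrated probabilities; no significance testing
  is attempted, and cross-sample normalization is out of scope.
* The half-binder filter can zero a true breakpoint's row when a strike
  crosses it; the break terms usually keep the candidate near the top, but
  single-probe evidence is lost in that case — an inherent property of the
  zeroing rule.
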