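"""Independent reference scorer: a literal, branch-by-branch transcription
of the published breakpoint-scoring pseudocode.  Kept free of any package
imports so it cannot share a defect with the production implementation."""


def score_pseudocode(
    A1,
    A2,
    B1,
    B2,
    len_A1,
    len_A2,
    len_B1,
    len_B2,
    chimeric_score,
    chimeric_cutoff=3.0,
    max_break_score=1.5,
    adjusted_to_max=6.0,
):
    if len_B1 == 0:
        fusion_score = 0.1
    elif (A1 > A2 and B2 < B1 and len_A2 <= 1 and len_B2 <= 1) or (
        A1 < A2 and B2 > B1 and len_A2 <= 1 and len_B2 <= 1
    ):
        fusion_score = 0.1
    elif A1 < A2 and B2 > B1 and len_A1 <= 1 and len_B1 <= 1:
        fusion_score = 0.1
    elif (A1 > A2 and B1 < B2 and len_B2 <= 1) or (A1 < A2 and B1 > B2 and len_A2 <= 1):
        fusion_score = 0.1
    else:
        if chimeric_score == adjusted_to_max:  # handles single-strong-probe enhancement
            fusion_score = chimeric_score
        else:
            fusion_score = min(chimeric_score, chimeric_cutoff)
            break_score_A = min(abs(A2 - A1), max_break_score)
            break_score_B = min(abs(B2 - B1), max_break_score)
            fusion_score = fusion_score + break_score_A + break_score_B
    return fusion_score


def which_branch(A1, A2, B1, B2, len_A1, len_A2, len_B1, len_B2, chimeric_score, adjusted_to_max=6.0):
    """Index (1-5) of the branch the pseudocode takes, for coverage checks."""
    if len_B1 == 0:
        return 1
    if ((A1 > A2 and B2 < B1) or (A1 < A2 and B2 > B1)) and len_A2 <= 1 and len_B2 <= 1:
        return 2
    if A1 < A2 and B2 > B1 and len_A1 <= 1 and len_B1 <= 1:
        return 3
    if (A1 > A2 and B1 < B2 and len_B2 <= 1) or (A1 < A2 and B1 > B2 and len_A2 <= 1):
        return 4
    return 5


def random_breakpoint_inputs(rng, n):
    """Randomized scorer inputs designed to reach every branch: rounded
    means (so exact ties occur), small segment lengths including empty B1,
    and chimeric values mixing 0, the 6.0 sentinel, and continuous draws."""
    out = []
    for _ in range(n):
        means = [round(float(rng.uniform(0, 4)), 1) for _ in range(4)]
        if rng.random() < 0.3:  # force ties between some means
            means[int(rng.integers(4))] = means[int(rng.integers(4))]
        len_a1 = int(rng.integers(1, 5))
        len_a2 = int(rng.integers(0, 5))
        len_b1 = int(rng.integers(0, 5))
        len_b2 = int(rng.integers(1, 5))
        u = rng.random()
        if u < 0.15:
            chim = 0.0
        elif u < 0.3:
            chim = 6.0
        else:
            chim = float(rng.uniform(0, 10))
        out.append((*means, len_a1, len_a2, len_b1, len_b2, chim))
    return out
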