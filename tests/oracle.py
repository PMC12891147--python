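"""Naive reference implementation of the adjusted sum score.

Written directly from the rule statements, operating on a dense length-15
score vector with explicit index loops, so it can serve as an independent
check of the package implementation.
"""

import math

N = 15
MINIMAL = -0.5


def oracle_olvfss(scores):
    """scores: sequence of 15 per-level values in craniocaudal order."""
    scores = list(scores)
    assert len(scores) == N

    # A minimal next to a vertebra scored -1.0 or worse contributes nothing.
    suppressed = set()
    for i in range(N):
        if scores[i] == MINIMAL:
            if i > 0 and scores[i - 1] <= -1.0:
                suppressed.add(i)
            elif i < N - 1 and scores[i + 1] <= -1.0:
                suppressed.add(i)

    total = 0.0
    for i in range(N):
        if scores[i] != MINIMAL:
            total += scores[i]

    # Maximal runs of adjacent surviving minimals: two count as one, three
    # as two, generally ceil(k/2) units of -0.5.
    i = 0
    while i < N:
        if scores[i] == MINIMAL and i not in suppressed:
            k = 0
            while i < N and scores[i] == MINIMAL and i not in suppressed:
                k += 1
                i += 1
            total += MINIMAL * math.ceil(k / 2) if k > 1 else MINIMAL
        else:
            i += 1
    return total
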