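"""Brute-force reference implementations used to cross-check the package.

Everything here is deliberately naive (quadratic pair enumeration,
definition-driven subsequence search, bp-resolution bitmasks) and shares no
code with the implementations under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_signature(records, max_d=20):
    """O(n^2) all-pairs ping-pong overlap histogram.

    ``records`` is an iterable of (pos5, strand, count).  Returns the
    normalised fractions h[0..max_d-1] for overlap d = 1..max_d, or None if
    there are no pairs.
    """
    w = [0.0] * max_d
    recs = list(records)
    for s_pos, s_strand, s_cnt in recs:
        if s_strand != "+":
            continue
        for a_pos, a_strand, a_cnt in recs:
            if a_strand != "-":
                continue
            d = a_pos - s_pos + 1
            if 1 <= d <= max_d:
                w[d - 1] += s_cnt * a_cnt
    total = sum(w)
    if total == 0:
        return None
    return np.array(w) / total


def _score(scores, i, j):
    return sum(scores[i:j])


def _all_proper_subs_lower(scores, i, j):
    s = _score(scores, i, j)
    for a in range(i, j):
        for b in range(a + 1, j + 1):
            if (a, b) != (i, j) and _score(scores, a, b) >= s:
                return False
    return True


def exhaustive_maximal_subsequences(scores):
    """All maximal scoring subsequences straight from the definition.

    A positive-scoring run [i, j) is maximal iff (1) every proper
    subsequence of it scores strictly lower and (2) no proper supersequence
    satisfying (1) scores at least as high.  O(n^4); for tiny inputs only.
    """
    n = len(scores)
    cands = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n + 1)
        if _score(scores, i, j) > 0 and _all_proper_subs_lower(scores, i, j)
    ]
    out = []
    for i, j in cands:
        s = _score(scores, i, j)
        dominated = any(
            (a <= i and j <= b and (a, b) != (i, j) and _score(scores, a, b) >= s)
            for a, b in cands
        )
        if not dominated:
            out.append((i, j, float(_score(scores, i, j))))
    return sorted(out)


def union_length_bitmask(intervals, genome_bp):
    """Union bp of intervals on one chromosome via an explicit bp mask."""
    mask = np.zeros(genome_bp, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())
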