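"""Independent reference scorer for cyclic-profile local alignment.

Top-down recursion with memoization, structurally unlike the production
bottom-up kernel: gap runs are enumerated explicitly by length, deletion
runs are capped at n-1 columns (a full-cycle deletion returns to the same
column at pure cost and can never improve a maximum-score alignment when
penalties are positive).  Alignments start and end with a match; insertion
and deletion runs are never adjacent.
"""

from functools import lru_cache

import numpy as np


def brute_force_score(codes, W, gap_open, gap_extend):
    """Maximum local alignment score of codes against the cyclic profile W."""
    N = len(codes)
    n = W.shape[1]
    if N == 0:
        return 0.0

    def w(i, c):  # 1-based seq pos, 0-based column
        b = codes[i - 1]
        return 0.0 if b >= 4 else W[b, c]

    @lru_cache(maxsize=None)
    def match(i, c):
        """Best alignment ending with a match of seq pos i to column c."""
        here = w(i, c)
        best = here  # start fresh at (i, c)
        cm1 = (c - 1) % n
        if i >= 2:
            prev = match(i - 1, cm1)
            if prev > 0 and here + prev > best:
                best = here + prev
            # insertion run of g sequence bases before this match
            for g in range(1, i - 1):
                prev = match(i - 1 - g, cm1)
                cost = gap_open + (g - 1) * gap_extend
                if prev > 0 and here + prev - cost > best:
                    best = here + prev - cost
            # deletion run of g period columns before this match
            for g in range(1, n):
                prev = match(i - 1, (c - 1 - g) % n)
                cost = gap_open + (g - 1) * gap_extend
                if prev > 0 and here + prev - cost > best:
                    best = here + prev - cost
        return best

    best = 0.0
    for i in range(1, N + 1):
        for c in range(n):
            s = match(i, c)
            if s > best:
                best = s
    match.cache_clear()
    return best
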