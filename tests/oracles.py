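"""Independent brute-force oracles used to check the optimized implementations.

These deliberately use the slowest, most transparent formulation of each
computation so they share no code path with the package.
"""

_SCORE = {"A": 1, "N": -1, "T": -2, "G": -2, "C": -2}


def brute_force_polyA(seq, search_start=0, max_dist=15):
    """All-substrings enumeration of the poly(A) region.

    Finds the maximum-scoring substring of ``seq[search_start:]`` (ties:
    larger end coordinate, then greater length), then applies the
    acceptance rules (score > 0, end within ``max_dist`` of the read
    end).  Returns ((start, end), score) or None.
    """
    n = len(seq)
    best = None  # (score, end, length, start)
    for i in range(search_start, n):
        running = 0
        for j in range(i + 1, n + 1):
            running += _SCORE[seq[j - 1]]
            key = (running, j, j - i)
            if best is None or key > (best[0], best[1], best[2]):
                best = (running, j, j - i, i)
    if best is None or best[0] <= 0:
        return None
    score, end, _, start = best
    if n - end > max_dist:
        return None
    return (start, end), score


def smith_waterman_score(target, query, match=1, mismatch=-1, gap=-2):
    """Plain O(nm) Smith-Waterman best local-alignment score (linear gaps)."""
    n, m = len(target), len(query)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        curr = [0] * (m + 1)
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if target[i - 1] == query[j - 1] else mismatch)
            curr[j] = max(0, diag, prev[j] + gap, curr[j - 1] + gap)
            if curr[j] > best:
                best = curr[j]
        prev = curr
    return best
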