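"""Independent brute-force oracle for local alignment.

A plain three-state affine-gap Smith-Waterman implemented with explicit
Python loops, sharing no code with the package's alignment engine. A gap of
length k costs ``gap_open + k * gap_extend`` (same convention the package
documents). Besides the optimal score, the oracle can enumerate every
co-optimal local alignment and report the set of (identity, columns,
query-span) summaries those alignments realize, so tests can assert that
the implementation's reported identity is achievable by *some* optimal
alignment rather than relying on matching tie-breaks.
"""

from __future__ import annotations

NEG = float("-inf")


def _score(x: str, y: str, match: float, mismatch: float) -> float:
    return match if (x == y and x != "N") else mismatch


def sw_matrices(a: str, b: str, match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0):
    """Fill the M (aligned pair), X (gap in a) and Y (gap in b) matrices."""
    n, m = len(a), len(b)
    first = -(gap_open + gap_extend)
    ext = -gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = _score(ai, b[j - 1], match, mismatch)
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i][j - 1] + first, Y[i][j - 1] + first, X[i][j - 1] + ext)
            Y[i][j] = max(M[i - 1][j] + first, X[i - 1][j] + first, Y[i - 1][j] + ext)
    return M, X, Y


def sw_score(a: str, b: str, **kw) -> float:
    """Optimal local alignment score (0 for two sequences with no positive pair)."""
    M, _, _ = sw_matrices(a, b, **kw)
    best = max(max(row) for row in M)
    return max(best, 0.0)


def optimal_summaries(a: str, b: str, match=2.0, mismatch=-3.0,
                      gap_open=5.0, gap_extend=2.0, max_paths=20000):
    """Summaries (identity, columns, query_span) of every optimal alignment.

    Enumerates all co-optimal tracebacks; intended for short sequences.
    """
    kw = dict(match=match, mismatch=mismatch, gap_open=gap_open, gap_extend=gap_extend)
    M, X, Y = sw_matrices(a, b, **kw)
    best = max(max(max(row) for row in M), 0.0)
    if best == 0.0:
        return best, {(0.0, 0, 0)}
    first = -(gap_open + gap_extend)
    ext = -gap_extend
    summaries = set()
    stack = []
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if M[i][j] == best:
                stack.append(("M", i, j, 0, 0, i))  # state, i, j, matches, cols, q_end
    matrices = {"M": M, "X": X, "Y": Y}
    seen = 0
    while stack:
        state, i, j, matches, cols, q_end = stack.pop()
        seen += 1
        if seen > max_paths:
            raise RuntimeError("too many co-optimal paths")
        if state == "M":
            s = _score(a[i - 1], b[j - 1], match, mismatch)
            matched = matches + (1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else 0)
            prev = M[i][j] - s
            ncols = cols + 1
            if abs(prev) < 1e-9:
                # local alignment starts at this column
                summaries.add((100.0 * matched / ncols, ncols, q_end - (i - 1)))
            else:
                for pstate in ("M", "X", "Y"):
                    val = matrices[pstate][i - 1][j - 1]
                    if val != NEG and abs(val - prev) < 1e-9:
                        stack.append((pstate, i - 1, j - 1, matched, ncols, q_end))
        elif state == "X":  # gap in a, consumes b[j-1]
            for pstate, step in (("M", first), ("Y", first), ("X", ext)):
                val = matrices[pstate][i][j - 1]
                if val != NEG and abs(val + step - X[i][j]) < 1e-9:
                    stack.append((pstate, i, j - 1, matches, cols + 1, q_end))
        else:  # Y: gap in b, consumes a[i-1]
            for pstate, step in (("M", first), ("X", first), ("Y", ext)):
                val = matrices[pstate][i - 1][j]
                if val != NEG and abs(val + step - Y[i][j]) < 1e-9:
                    stack.append((pstate, i - 1, j, matches, cols + 1, q_end))
    return best, summaries


def shared_kmer_count(a: str, b: str, k: int) -> int:
    """Exhaustive count of distinct k-mers occurring in both sequences."""
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb)
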