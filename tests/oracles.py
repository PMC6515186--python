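"""Independent brute-force oracles used by the test suite.

Each oracle deliberately uses a different formulation from the package
implementation it checks, so agreement is evidence of correctness rather
than repetition.
"""

from __future__ import annotations

from collections import Counter

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def enumerate_max_pairing(seq: str, min_loop: int = 3) -> int:
    """Maximum nested pairing by explicit enumeration (no DP table).

    Recursively decides the fate of the leftmost position of each
    interval, enumerating every valid nested pair set.
    """

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        options = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                options.append(1 + best(i + 1, k - 1) + best(k + 1, j))
        return max(options)

    return best(0, len(seq) - 1)


def loop_decomposition(pairs: set[tuple[int, int]], n: int):
    """Recursive nesting-tree traversal -> (letters, element counts).

    Starts from the exterior and descends pair by pair; helix letters are
    decided when the loop under the helix is reached.
    """
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    letters = [""] * (n + 2)
    counts: Counter[str] = Counter()

    def scan(a: int, b: int):
        """Children pairs and unpaired runs strictly between a and b."""
        kids, runs = [], []
        p, run = a + 1, []
        while p < b:
            if p in partner:
                if run:
                    runs.append(tuple(run))
                    run = []
                kids.append((p, partner[p]))
                p = partner[p] + 1
            else:
                run.append(p)
                p += 1
        if run:
            runs.append(tuple(run))
        return kids, runs

    def descend(i: int, j: int):
        helix = [(i, j)]
        while (i + 1 in partner) and partner[i + 1] == j - 1:
            i, j = i + 1, j - 1
            helix.append((i, j))
        kids, runs = scan(i, j)
        if not kids:
            kind = "L"
        elif len(kids) == 1:
            kind = "I" if len(runs) == 2 else "G"
        else:
            kind = "M"
        counts[kind] += 1
        for run in runs:
            for p in run:
                letters[p] = kind
        hletter = "H" if kind == "L" else "D"
        counts[hletter] += 1
        for x, y in helix:
            letters[x] = hletter
            letters[y] = hletter
        for ci, cj in kids:
            descend(ci, cj)

    kids, runs = scan(0, n + 1)
    for run in runs:
        counts["S"] += 1
        for p in run:
            letters[p] = "S"
    for ci, cj in kids:
        descend(ci, cj)
    return "".join(letters[1 : n + 1]), {
        k: counts.get(k, 0) for k in "SHLIGDM"
    }


def affine_alignment_score(
    a: str, b: str, match: float, mismatch: float, open_: float, extend: float
) -> float:
    """Optimal global affine-gap score via a match-anchored O(n^2 m^2) DP.

    M[i][j] = best score of an alignment of a[:i], b[:j] whose last column
    aligns a_i with b_j; transitions jump over a gap block on each side,
    charged open + extend * length per non-empty block.  Entirely
    different from the three-state band recurrences it cross-checks.
    """

    def gap(t: int) -> float:
        return 0.0 if t == 0 else open_ + extend * t

    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            best = NEG
            for k in range(i):
                for l in range(j):
                    prev = 0.0 if (k == 0 and l == 0) else M[k][l]
                    if prev == NEG:
                        continue
                    cand = prev - gap(i - 1 - k) - gap(j - 1 - l)
                    if cand > best:
                        best = cand
            M[i][j] = s + best
    total = -gap(n) - gap(m)  # the matchless alignment
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i][j] > NEG:
                total = max(total, M[i][j] - gap(n - i) - gap(m - j))
    return total
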