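"""Progressive multiple alignment of secondary structure strings (MSS$A).

Structure strings are globally aligned like protein sequences, but with an
identity substitution scheme: a letter only ever matches itself, and no
residue-specific or hydrophilic gap adjustments apply.  Pairwise alignment
is Needleman-Wunsch/Gotoh with affine gaps (a gap of length L costs
``gap_open + L * gap_extend``).  The multiple alignment is progressive:
a neighbor-joining guide tree over ``d = 1 - identity`` distances fixes
the merge order, profiles are merged leaf-to-root, and once a gap is
inserted it is never removed.

Externally produced Clustal alignments can be read back in, so the same
downstream domain analysis can run on an alignment from another tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

try:  # fast guide-tree distances; the package's own aligner is the fallback
    import edlib as _edlib
except ImportError:  # pragma: no cover
    _edlib = None

__all__ = [
    "SubstitutionScheme",
    "GuideNode",
    "MultipleAlignment",
    "pairwise_align",
    "progressive_align",
    "neighbor_joining",
    "identity_distance_matrix",
    "read_clustal",
    "write_clustal",
]

GAP = "-"


@dataclass(frozen=True)
class SubstitutionScheme:
    """Identity substitution scores and affine gap penalties."""

    match: float = 10.0
    mismatch: float = 0.0
    gap_open: float = 10.0
    gap_extend: float = 0.2

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass(frozen=True)
class GuideNode:
    """Binary guide-tree node; leaves carry a label, joins a height."""

    label: str | None = None
    left: "GuideNode | None" = None
    right: "GuideNode | None" = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.left.leaves() + self.right.leaves()  # type: ignore[union-attr]


@dataclass
class MultipleAlignment:
    """Gapped rows keyed by label; all rows share one column count."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, label: str) -> str:
        return self.rows[label].replace(GAP, "")

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows.values()]


# ---------------------------------------------------------------------------
# Pairwise Gotoh alignment
# ---------------------------------------------------------------------------

_NEG = -1e30


def _gotoh(S: np.ndarray, open_: float, extend: float):
    """Affine-gap global alignment over a precomputed n x m score matrix.

    Returns (score, path) where path is a list of (i, j) with ``None``
    marking a gap on that side.  Traceback prefers diagonal over up (gap
    in the second sequence) over left, so it is deterministic.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(open_ + extend * i)
    for j in range(1, m + 1):
        Y[0, j] = -(open_ + extend * j)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = best_prev + S[i - 1, :]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - (open_ + extend),
            X[i - 1, 1:] - extend,
        )
        # Y has an in-row dependence; roll it manually
        for j in range(1, m + 1):
            Y[i, j] = max(
                max(M[i, j - 1], X[i, j - 1]) - (open_ + extend),
                Y[i, j - 1] - extend,
            )
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])), key=lambda t: t[1]
    )[0]
    score = max(M[n, m], X[n, m], Y[n, m])
    path: list[tuple[int | None, int | None]] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            prev = M[i - 1, j - 1] + S[i - 1, j - 1]
            if abs(M[i, j] - prev) <= eps:
                state = "M"
            elif abs(M[i, j] - (X[i - 1, j - 1] + S[i - 1, j - 1])) <= eps:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            path.append((i - 1, None))
            if abs(X[i, j] - (M[i - 1, j] - (open_ + extend))) <= eps:
                state = "M"
            elif abs(X[i, j] - (Y[i - 1, j] - (open_ + extend))) <= eps:
                state = "Y"
            else:
                state = "X"
            i -= 1
        else:
            path.append((None, j - 1))
            if abs(Y[i, j] - (M[i, j - 1] - (open_ + extend))) <= eps:
                state = "M"
            elif abs(Y[i, j] - (X[i, j - 1] - (open_ + extend))) <= eps:
                state = "X"
            else:
                state = "Y"
            j -= 1
        if i == 0 and j == 0:
            break
    path.reverse()
    return float(score), path


def _letter_score_matrix(a: str, b: str, scheme: SubstitutionScheme) -> np.ndarray:
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return np.where(
        av[:, None] == bv[None, :], scheme.match, scheme.mismatch
    ).astype(float)


def pairwise_align(
    a: str, b: str, scheme: SubstitutionScheme | None = None
) -> tuple[str, str, float]:
    """Optimal global affine-gap alignment of two strings."""
    if not a or not b:
        raise ValueError("strings must be non-empty")
    scheme = scheme or SubstitutionScheme()
    S = _letter_score_matrix(a, b, scheme)
    score, path = _gotoh(S, scheme.gap_open, scheme.gap_extend)
    ga = "".join(a[i] if i is not None else GAP for i, _ in path)
    gb = "".join(b[j] if j is not None else GAP for _, j in path)
    return ga, gb, score


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------


def _pair_identity_distance(a: str, b: str, scheme: SubstitutionScheme) -> float:
    if _edlib is not None:
        d = _edlib.align(a, b, task="distance")["editDistance"]
        return d / max(len(a), len(b))
    ga, gb, _ = pairwise_align(a, b, scheme)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
    return 1.0 - matches / len(ga)


def identity_distance_matrix(
    strings: Sequence[str], scheme: SubstitutionScheme | None = None
) -> np.ndarray:
    """Symmetric ``1 - identity-fraction`` distances."""
    scheme = scheme or SubstitutionScheme()
    n = len(strings)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _pair_identity_distance(
                strings[i], strings[j], scheme
            )
    return D


def neighbor_joining(labels: Sequence[str], D: np.ndarray) -> GuideNode:
    """Neighbor joining with deterministic tie-breaking.

    Equal Q values resolve to the join whose (sorted) label pair is
    lexicographically smallest.  The final three (or two) nodes are joined
    into a root, so the result is a rooted binary merge order.
    """
    n = len(labels)
    if n < 1:
        raise ValueError("need at least one label")
    nodes = [GuideNode(label=l) for l in labels]
    keys = [str(l) for l in labels]
    # preallocated scratch matrix: up to n-1 internal joins
    big = np.zeros((2 * n, 2 * n))
    big[:n, :n] = D
    active = list(range(n))
    height = 0.0
    while len(active) > 2:
        m = len(active)
        idx = np.array(active)
        sub = big[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), i, j)
            for i, j in cand
            if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        height += 1.0
        joined = GuideNode(left=nodes[i], right=nodes[j], height=height)
        dist_new = 0.5 * (big[i, idx] + big[j, idx] - big[i, j])
        new = len(nodes)
        nodes.append(joined)
        keys.append(min(keys[i], keys[j]))
        big[new, idx] = dist_new
        big[idx, new] = dist_new
        big[new, new] = 0.0
        active = [x for x in active if x not in (i, j)] + [new]
    while len(active) > 1:
        i, j = active[0], active[1]
        height += 1.0
        joined = GuideNode(left=nodes[i], right=nodes[j], height=height)
        nodes.append(joined)
        keys.append(min(keys[i], keys[j]))
        active = active[2:] + [len(nodes) - 1]
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# Progressive profile alignment
# ---------------------------------------------------------------------------

def _profile_counts(rows: Sequence[str], alphabet: Sequence[str]) -> np.ndarray:
    idx = {ch: k for k, ch in enumerate(alphabet)}
    L = len(rows[0])
    counts = np.zeros((len(alphabet), L))
    for r in rows:
        for j, ch in enumerate(r):
            counts[idx[ch], j] += 1
    return counts


def _merge_profiles(
    rows_a: dict[str, str],
    rows_b: dict[str, str],
    scheme: SubstitutionScheme,
) -> dict[str, str]:
    alphabet = sorted({c for r in (*rows_a.values(), *rows_b.values()) for c in r} - {GAP})
    alphabet.append(GAP)
    fa = _profile_counts(list(rows_a.values()), alphabet) / len(rows_a)
    fb = _profile_counts(list(rows_b.values()), alphabet) / len(rows_b)
    k = len(alphabet)
    subst = np.full((k, k), scheme.mismatch)
    np.fill_diagonal(subst, scheme.match)
    subst[-1, :] = 0.0  # gaps in an existing profile column score nothing
    subst[:, -1] = 0.0
    S = fa.T @ subst @ fb
    _, path = _gotoh(S, scheme.gap_open, scheme.gap_extend)
    merged: dict[str, str] = {}
    for label, row in rows_a.items():
        merged[label] = "".join(row[i] if i is not None else GAP for i, _ in path)
    for label, row in rows_b.items():
        merged[label] = "".join(row[j] if j is not None else GAP for _, j in path)
    return merged


def progressive_align(
    ss_strings: Mapping[str, str] | Iterable[tuple[str, str]],
    scheme: SubstitutionScheme | None = None,
) -> MultipleAlignment:
    """Align a population of structure strings leaf-to-root.

    Deterministic for a fixed input order.  A single input is returned
    as-is with a warning.
    """
    items = (
        list(ss_strings.items())
        if isinstance(ss_strings, Mapping)
        else list(ss_strings)
    )
    if not items:
        raise ValueError("no strings to align")
    labels = [l for l, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    scheme = scheme or SubstitutionScheme()
    if len(items) == 1:
        warnings.warn("single input string: returned unaligned", stacklevel=2)
        return MultipleAlignment(rows=dict(items))
    strings = dict(items)
    D = identity_distance_matrix([s for _, s in items], scheme)
    tree = neighbor_joining(labels, D)

    # iterative post-order merge (guide trees can be deep)
    done: dict[int, dict[str, str]] = {}
    stack: list[tuple[GuideNode, bool]] = [(tree, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf:
            done[id(node)] = {node.label: strings[node.label]}  # type: ignore[index]
        elif not expanded:
            stack.append((node, True))
            stack.append((node.left, False))  # type: ignore[arg-type]
            stack.append((node.right, False))  # type: ignore[arg-type]
        else:
            left = done.pop(id(node.left))
            right = done.pop(id(node.right))
            done[id(node)] = _merge_profiles(left, right, scheme)
    merged = done[id(tree)]
    return MultipleAlignment(rows={l: merged[l] for l in labels})


# ---------------------------------------------------------------------------
# Clustal I/O (via Biopython)
# ---------------------------------------------------------------------------


def read_clustal(path: str | Path) -> MultipleAlignment:
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "clustal")
    return MultipleAlignment(rows={rec.id: str(rec.seq) for rec in aln})


def write_clustal(aln: MultipleAlignment, path: str | Path) -> None:
    from Bio import AlignIO
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=label, description="") for label, row in aln.rows.items()]
    )
    AlignIO.write(msa, str(path), "clustal")
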