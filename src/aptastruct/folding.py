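"""Dominant and suboptimal self-hybridized structures.

Folding proper is delegated to a pluggable engine.  Three engines ship:

* :class:`ViennaRNAEngine` — an mfold-compatible thermodynamic engine built
  on the ViennaRNA python bindings with the DNA (Mathews 2004) parameter
  set, a monovalent-equivalent salt correction for the screening buffer,
  Zuker-style suboptimal structures, and the classic suboptimal-window
  distinctness filter.
* :class:`BaselineEngine` — a self-contained maximum-pairing folder
  (no energy model; NOT a thermodynamic prediction) so every downstream
  stage runs with no external dependency.
* :class:`CTDirectoryEngine` — reads pre-computed mfold/UNAFold CT files,
  letting an externally run folding server drive the analysis.

Whatever the engine, structures are validated (unique partners, no
pseudoknots, hairpin loops >= 3 nt), sorted by free energy and labelled
S1..Sn; the 5% free-energy window then selects the suboptimal set.
"""

from __future__ import annotations

import glob
import math
import os
import re
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .library_synth import SequenceRecord

__all__ = [
    "BasePairSet",
    "FoldedStructure",
    "FoldingConditions",
    "FoldingEngine",
    "BaselineEngine",
    "ViennaRNAEngine",
    "CTDirectoryEngine",
    "fold",
    "select_suboptimal",
    "baseline_fold",
    "parse_ct",
    "parse_dotbracket",
    "write_dotbracket",
]

#: allowed pairs in the baseline folder (Watson-Crick plus G.T wobble; the
#: wobble is required by the 3'-flank hairpin stem, whose 57.65 pair is G.T)
_BASELINE_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}

MIN_HAIRPIN_LOOP = 3


@dataclass(frozen=True)
class BasePairSet:
    """A validated, pseudoknot-free set of base pairs over 1..length."""

    pairs: frozenset[tuple[int, int]]
    length: int

    def __post_init__(self) -> None:
        seen: dict[int, tuple[int, int]] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair {(i, j)} out of range for length {self.length}")
            if j - i < MIN_HAIRPIN_LOOP + 1:
                raise ValueError(
                    f"pair {(i, j)} closes a hairpin loop shorter than {MIN_HAIRPIN_LOOP} nt"
                )
            for x in (i, j):
                if x in seen:
                    raise ValueError(
                        f"base {x} pairs twice: in {seen[x]} and {(i, j)}"
                    )
                seen[x] = (i, j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1 :]:
                if k > j:
                    break
                if k < j < l:  # i < k by sort order
                    raise ValueError(
                        f"pseudoknot: pairs {(i, j)} and {(k, l)} cross"
                    )

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FoldedStructure:
    """One fold of one sequence, ranked by free energy (S1 = most negative)."""

    sequence_id: str
    pairs: BasePairSet
    dG: float
    rank_label: str = "S1"
    pseudo_energy: bool = False  # True when dG is the baseline pair-count proxy

    @property
    def label(self) -> str:
        return f"{self.sequence_id}.{self.rank_label}"


@dataclass(frozen=True)
class FoldingConditions:
    """Buffer and selection settings (defaults mimic the screening buffer)."""

    sodium: float = 152.0  # mM
    magnesium: float = 4.0  # mM
    temperature: float = 23.0  # Celsius
    subopt_window: float = 0.05  # fraction of |dG(S1)|

    def __post_init__(self) -> None:
        if self.subopt_window < 0:
            raise ValueError("subopt_window must be >= 0")


class FoldingEngine(Protocol):
    """Adapter contract: sequence + conditions in, >=1 (pairs, dG) out."""

    def fold_raw(
        self, record: SequenceRecord, conditions: FoldingConditions
    ) -> list[tuple[BasePairSet, float]]: ...


def _dotbracket_key(pairs: BasePairSet) -> str:
    return write_dotbracket(pairs)


def fold(
    record: SequenceRecord,
    conditions: FoldingConditions | None = None,
    engine: FoldingEngine | None = None,
) -> list[FoldedStructure]:
    """Run an engine and return validated structures labelled S1..Sn.

    Structures are sorted by ascending dG; ties broken by fewer pairs, then
    lexicographic dot-bracket, so labelling is deterministic.
    """
    conditions = conditions or FoldingConditions()
    engine = engine or BaselineEngine()
    raw = engine.fold_raw(record, conditions)
    if not raw:
        raise ValueError(f"engine returned no structures for {record.id!r}")
    for bps, _ in raw:
        if bps.length != len(record.sequence):
            raise ValueError(
                f"engine structure length {bps.length} != sequence length "
                f"{len(record.sequence)} for {record.id!r}"
            )
    ordered = sorted(
        raw, key=lambda t: (t[1], len(t[0]), _dotbracket_key(t[0]))
    )
    return [
        FoldedStructure(
            sequence_id=record.id,
            pairs=bps,
            dG=dG,
            rank_label=f"S{r + 1}",
            pseudo_energy=getattr(engine, "pseudo_energy", False),
        )
        for r, (bps, dG) in enumerate(ordered)
    ]


def select_suboptimal(
    structures: Sequence[FoldedStructure], window: float
) -> list[FoldedStructure]:
    """Keep S1 plus every fold with ``|dG - dG1| <= window * |dG1|``.

    Survivors are relabelled S1..Sn in dG order.  With dG1 = 0 (an
    unfolded dominant structure) the window degenerates to width zero.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not structures:
        raise ValueError("no structures to select from")
    ordered = sorted(
        structures, key=lambda s: (s.dG, len(s.pairs), _dotbracket_key(s.pairs))
    )
    dg1 = ordered[0].dG
    cutoff = window * abs(dg1)
    kept = [s for s in ordered if abs(s.dG - dg1) <= cutoff + 1e-9]
    return [replace(s, rank_label=f"S{r + 1}") for r, s in enumerate(kept)]


# ---------------------------------------------------------------------------
# Baseline folder: maximum nested pairing (no energy model)
# ---------------------------------------------------------------------------


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _BASELINE_PAIRS


def baseline_fold(
    seq: SequenceRecord | str, min_loop: int = MIN_HAIRPIN_LOOP
) -> FoldedStructure:
    """Maximum-cardinality nested pairing over {A.T, G.C, G.T}.

    Dynamic program over intervals with a deterministic traceback: position
    i prefers pairing with the largest admissible j, otherwise stays
    unpaired; bifurcation happens implicitly at that pairing point.  The
    reported dG is ``-(number of pairs)``, a pseudo-energy used only for
    ranking (``pseudo_energy=True``).
    """
    if isinstance(seq, str):
        seq = SequenceRecord(id="seq", sequence=seq)
    s = seq.sequence
    if not s:
        raise ValueError("empty sequence")
    n = len(s)
    # N[i][j]: max pairs in s[i..j], 0-based inclusive
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    left = N[i + 1][k - 1] if k - 1 > i else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            N[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = N[i][j]
        chosen = None
        for k in range(j, i + min_loop, -1):  # largest admissible j first
            if _can_pair(s[i], s[k]):
                left = N[i + 1][k - 1] if k - 1 > i else 0
                right = N[k + 1][j] if k + 1 <= j else 0
                if 1 + left + right == target:
                    chosen = k
                    break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.append((i + 1, chosen + 1))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))

    bps = BasePairSet(pairs=frozenset(pairs), length=n)
    return FoldedStructure(
        sequence_id=seq.id, pairs=bps, dG=-float(len(pairs)), pseudo_energy=True
    )


class BaselineEngine:
    """Engine adapter around :func:`baseline_fold` (single structure)."""

    pseudo_energy = True

    def __init__(self, min_loop: int = MIN_HAIRPIN_LOOP):
        self.min_loop = min_loop

    def fold_raw(self, record, conditions):
        st = baseline_fold(record, min_loop=self.min_loop)
        return [(st.pairs, st.dG)]


# ---------------------------------------------------------------------------
# ViennaRNA adapter (mfold-compatible thermodynamic engine)
# ---------------------------------------------------------------------------


@contextmanager
def _silence_fd2():
    # ViennaRNA's subopt_zuker prints spurious diagnostics to fd 2
    saved = os.dup(2)
    devnull = os.open(os.devnull, os.O_WRONLY)
    try:
        os.dup2(devnull, 2)
        yield
    finally:
        os.dup2(saved, 2)
        os.close(saved)
        os.close(devnull)


def _mfold_window_default(n: int) -> int:
    # classic suboptimal-window defaults by sequence length
    if n <= 30:
        return 0
    if n <= 49:
        return 1
    if n <= 119:
        return 2
    if n <= 199:
        return 3
    return 5


def mfold_window_filter(
    candidates: Sequence[tuple[BasePairSet, float]], window: int
) -> list[tuple[BasePairSet, float]]:
    """Distinctness filter over energy-sorted folds.

    A fold is kept only if it contributes more than ``window`` base pairs
    that are farther than ``window`` (in both indices) from every pair of
    every previously kept fold — the classic rule that turns the dense set
    of suboptimal folds into a small set of genuinely different ones.
    """
    kept: list[tuple[BasePairSet, float]] = []
    covered: set[tuple[int, int]] = set()
    for bps, dg in candidates:
        new = [
            (i, j)
            for (i, j) in bps.pairs
            if not any(
                (i + di, j + dj) in covered
                for di in range(-window, window + 1)
                for dj in range(-window, window + 1)
            )
        ]
        if not kept or len(new) > window:
            kept.append((bps, dg))
            covered |= set(bps.pairs)
    return kept


class ViennaRNAEngine:
    """mfold-compatible DNA folding via the ViennaRNA bindings.

    Uses the DNA (Mathews 2004) nearest-neighbor parameters, the requested
    temperature, and a monovalent-equivalent salt correction
    ``[Na+]eq = [Na+] + 120 * sqrt([Mg2+])`` (concentrations in mM).
    Suboptimal folds come from the Zuker best-fold-through-every-pair
    construction, restricted to the conditions' free-energy window and
    thinned by :func:`mfold_window_filter`.

    ``distinctness_window=None`` picks the classic length-dependent
    default (2 for a 69-nt strand).
    """

    pseudo_energy = False
    _params_loaded = False

    def __init__(self, distinctness_window: int | None = None):
        import RNA  # noqa: F401  -- fail fast when bindings are missing

        self._RNA = RNA
        self.distinctness_window = distinctness_window
        if not ViennaRNAEngine._params_loaded:
            RNA.params_load_DNA_Mathews2004()
            ViennaRNAEngine._params_loaded = True

    def fold_raw(self, record, conditions):
        RNA = self._RNA
        md = RNA.md()
        md.temperature = conditions.temperature
        md.salt = (conditions.sodium + 120.0 * math.sqrt(conditions.magnesium)) / 1000.0
        fc = RNA.fold_compound(record.sequence, md)
        mfe_ss, mfe = fc.mfe()
        with _silence_fd2():
            subs = fc.subopt_zuker()
        n = len(record.sequence)
        seen: dict[str, float] = {}
        for s in subs:
            e = round(float(s.energy), 2)
            if s.structure not in seen or e < seen[s.structure]:
                seen[s.structure] = e
        seen.setdefault(mfe_ss, round(float(mfe), 2))
        cutoff = mfe + conditions.subopt_window * abs(mfe) + 1e-6
        cands = sorted(
            (
                (parse_dotbracket(ss), e)
                for ss, e in seen.items()
                if e <= cutoff
            ),
            key=lambda t: (t[1], len(t[0]), _dotbracket_key(t[0])),
        )
        w = self.distinctness_window
        if w is None:
            w = _mfold_window_default(n)
        return mfold_window_filter(cands, w)


class CTDirectoryEngine:
    """Engine backed by pre-computed CT files.

    Looks up ``{id}.ct`` or ``{id}.S*.ct`` / ``{id}_*.ct`` in a directory,
    so structures folded by an external mfold/UNAFold run can drive the
    analysis verbatim.
    """

    pseudo_energy = False

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def fold_raw(self, record, conditions):
        hits = sorted(
            set(glob.glob(str(self.directory / f"{record.id}.ct")))
            | set(glob.glob(str(self.directory / f"{record.id}.*.ct")))
            | set(glob.glob(str(self.directory / f"{record.id}_*.ct")))
        )
        if not hits:
            raise FileNotFoundError(
                f"no CT file for {record.id!r} under {self.directory}"
            )
        out = []
        for path in hits:
            seq, st = parse_ct(path)
            if seq != record.sequence:
                raise ValueError(
                    f"CT file {path} sequence does not match record {record.id!r}"
                )
            out.append((st.pairs, st.dG))
        return out


# ---------------------------------------------------------------------------
# Format I/O: mfold CT and Vienna dot-bracket
# ---------------------------------------------------------------------------

_CT_DG = re.compile(r"d+G\s*=\s*(-?\d+\.?\d*)", re.IGNORECASE)


def parse_ct(path: str | Path) -> tuple[str, FoldedStructure]:
    """Parse an mfold/UNAFold connectivity table (first structure only)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: CT header must start with the length") from exc
    m = _CT_DG.search(lines[0])
    dg = float(m.group(1)) if m else 0.0
    name = lines[0].split()[-1] if len(header) > 1 and m else "structure"
    seq_chars = []
    pairing = [0] * (n + 1)
    for row, line in enumerate(lines[1 : n + 1], start=1):
        cols = line.split()
        if len(cols) < 6:
            raise ValueError(f"{path}: row {row} has fewer than 6 columns")
        idx = int(cols[0])
        if idx != row:
            raise ValueError(f"{path}: row {row} indexed as {idx}")
        seq_chars.append(cols[1].upper())
        pairing[row] = int(cols[4])
    if len(seq_chars) != n:
        raise ValueError(f"{path}: expected {n} body rows, got {len(seq_chars)}")
    pairs = set()
    for i in range(1, n + 1):
        j = pairing[i]
        if j == 0:
            continue
        if not (1 <= j <= n) or pairing[j] != i:
            raise ValueError(
                f"{path}: rows {i} and {j} disagree on pairing "
                f"({i}->{j} but {j}->{pairing[j] if 1 <= j <= n else '?'})"
            )
        if i < j:
            pairs.add((i, j))
    bps = BasePairSet(pairs=frozenset(pairs), length=n)
    st = FoldedStructure(sequence_id=str(name), pairs=bps, dG=dg)
    return "".join(seq_chars), st


def write_ct(
    sequence: str, structure: FoldedStructure, path: str | Path
) -> None:
    """Write a single-structure mfold-dialect CT file."""
    n = len(sequence)
    partner = structure.pairs.partner()
    lines = [f"{n}\tdG = {structure.dG:g}\t{structure.label}"]
    for i in range(1, n + 1):
        lines.append(
            f"{i}\t{sequence[i - 1]}\t{i - 1}\t{(i + 1) % (n + 1)}\t"
            f"{partner.get(i, 0)}\t{i}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def parse_dotbracket(text: str) -> BasePairSet:
    """Dot-bracket string -> base-pair set (single bracket tier)."""
    stack: list[int] = []
    pairs = set()
    for pos, c in enumerate(text.strip(), start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c not in ".":
            raise ValueError(f"unexpected character {c!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return BasePairSet(pairs=frozenset(pairs), length=len(text.strip()))


def write_dotbracket(pairs: BasePairSet) -> str:
    chars = ["."] * pairs.length
    for i, j in pairs.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)
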