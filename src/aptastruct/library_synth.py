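"""Synthetic ssDNA screening-library generation.

A screening library member is a 69-nt single strand built from two constant
primer-binding flanks around a 40-nt randomized insert
(5'-GGGACAGGGCTAGC-[40N]-GAGGCAAAGCTTCCG-3').  Two insert compositions are
modelled: *equibase* (25% each base) and *A-rich* (40% A, 20% C/G/T), the
latter motivated by the stronger adenine-gold interaction when panning
against gold nanorods.

The module also plants base-pair structures with an exact, prescribed
secondary-structure-element composition, so every downstream stage
(annotation, scoring, alignment, domain calling) can be exercised without a
thermodynamic folding engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "DNA_ALPHABET",
    "FLANK5",
    "FLANK3",
    "LibraryDesign",
    "SequenceRecord",
    "PlantedStructureSpec",
    "EQUIBASE_DESIGN",
    "ARICH_DESIGN",
    "generate_library",
    "plant_structure",
    "read_fasta",
    "write_fasta",
]

DNA_ALPHABET = "ACGT"

#: constant primer-binding flanks of the standard 69-nt design
FLANK5 = "GGGACAGGGCTAGC"
FLANK3 = "GAGGCAAAGCTTCCG"

#: Watson-Crick complements used when realizing planted base pairs
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class LibraryDesign:
    """A fixed-flank library with an i.i.d. randomized insert.

    ``composition`` maps each base to its draw probability in the variable
    segment; probabilities must sum to 1 (tolerance 1e-12).
    """

    flank5: str = FLANK5
    flank3: str = FLANK3
    variable_length: int = 40
    composition: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in DNA_ALPHABET}
    )
    name: str = "equibase"

    def __post_init__(self) -> None:
        for flank in (self.flank5, self.flank3):
            bad = [c for c in flank if c not in DNA_ALPHABET]
            if bad:
                raise ValueError(f"flank contains non-ACGT characters: {bad}")
        if self.variable_length < 0:
            raise ValueError("variable_length must be non-negative")
        if set(self.composition) - set(DNA_ALPHABET):
            raise ValueError(
                f"composition keys must be in {DNA_ALPHABET}: {sorted(self.composition)}"
            )
        total = float(sum(self.composition.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"composition probabilities sum to {total!r}, not 1")
        if any(p < 0 for p in self.composition.values()):
            raise ValueError("composition probabilities must be non-negative")

    @property
    def total_length(self) -> int:
        return len(self.flank5) + self.variable_length + len(self.flank3)

    @property
    def segments(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        """1-based inclusive spans (fixed5, variable, fixed3)."""
        a = len(self.flank5)
        b = a + self.variable_length
        return ((1, a), (a + 1, b), (b + 1, self.total_length))


EQUIBASE_DESIGN = LibraryDesign()
ARICH_DESIGN = LibraryDesign(
    composition={"A": 0.40, "C": 0.20, "G": 0.20, "T": 0.20}, name="arich"
)


@dataclass
class SequenceRecord:
    """One candidate strand with its flank/variable segmentation.

    ``segments`` holds 1-based inclusive spans (fixed5, variable, fixed3);
    it is ``None`` for sequences without the standard design (e.g. planted
    test structures of arbitrary length).
    """

    id: str
    sequence: str
    origin: str = "equibase"
    segments: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in DNA_ALPHABET]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"record {self.id!r}: non-ACGT character {char!r} at position {pos}"
            )
        if self.segments is not None:
            flat = [x for span in self.segments for x in span]
            expect = 1
            for start, stop in self.segments:
                if start != expect or stop < start - 1:
                    raise ValueError(
                        f"record {self.id!r}: segments {self.segments} do not tile 1..{len(self.sequence)}"
                    )
                expect = stop + 1
            if expect != len(self.sequence) + 1:
                raise ValueError(
                    f"record {self.id!r}: segments {self.segments} do not tile 1..{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def variable_segment(self) -> str:
        if self.segments is None or len(self.segments) != 3:
            raise ValueError("record has no flank/variable segmentation")
        start, stop = self.segments[1]
        return self.sequence[start - 1 : stop]


def generate_library(
    design: LibraryDesign, n: int, seed: int, id_prefix: str | None = None
) -> list[SequenceRecord]:
    """Draw ``n`` library members with i.i.d. variable bases.

    Same ``seed`` gives bit-identical output.  Record ids are
    ``{prefix}{0001..}`` with the prefix defaulting to the design name.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prefix = design.name if id_prefix is None else id_prefix
    rng = np.random.default_rng(seed)
    bases = np.array(list(DNA_ALPHABET))
    probs = np.array([design.composition.get(b, 0.0) for b in DNA_ALPHABET])
    draws = rng.choice(bases, size=(n, design.variable_length), p=probs)
    width = max(4, len(str(n)))
    records = []
    for i in range(n):
        var = "".join(draws[i])
        records.append(
            SequenceRecord(
                id=f"{prefix}{i + 1:0{width}d}",
                sequence=design.flank5 + var + design.flank3,
                origin=design.name,
                segments=design.segments,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Planted structures with exact element composition
# ---------------------------------------------------------------------------

_SSE_ORDER = "SHLIGDM"


@dataclass(frozen=True)
class PlantedStructureSpec:
    """Target element composition for a planted structure.

    ``element_counts`` is keyed by the 7 one-letter element codes
    (S single-stranded segment, H hairpin stem, L hairpin loop,
    I internal loop, G bulge, D duplex, M multi-branched loop).

    Structural bookkeeping forces several identities on any realizable
    count vector: every hairpin loop is closed by exactly one stem
    (H == L); every internal loop, bulge and multibranch loop is closed
    from outside by exactly one duplex helix (D == I + G + M); each
    multibranch join merges two branches (H >= M + 1 when M > 0); and the
    number of exterior single-stranded runs cannot exceed the number of
    root helices plus one.
    """

    length: int
    element_counts: Mapping[str, int]
    seed: int = 0

    def counts(self) -> dict[str, int]:
        c = {k: int(self.element_counts.get(k, 0)) for k in _SSE_ORDER}
        if any(v < 0 for v in c.values()):
            raise ValueError("element counts must be non-negative")
        extra = set(self.element_counts) - set(_SSE_ORDER)
        if extra:
            raise ValueError(f"unknown element codes: {sorted(extra)}")
        return c


class UnrealizableSpecError(ValueError):
    """Raised when no structure can realize the requested element counts."""


@dataclass
class _Fragment:
    # pairs are 1-based within the fragment
    length: int
    pairs: list[tuple[int, int]]

    def shifted(self, offset: int) -> list[tuple[int, int]]:
        return [(i + offset, j + offset) for i, j in self.pairs]


def _min_length(c: Mapping[str, int]) -> int:
    # hairpin unit 5 nt; internal-loop wrap +4; bulge wrap +3; multibranch
    # join +5 (closing pair + 3 spacer bases); each S run >= 1 nt
    return 5 * c["H"] + 4 * c["I"] + 3 * c["G"] + 5 * c["M"] + c["S"]


def plant_structure(spec: PlantedStructureSpec):
    """Construct a (sequence, base-pair set) realizing ``spec`` exactly.

    The returned pair set, decomposed by :func:`~aptastruct.sse_annotation.
    annotate_structure`, yields exactly ``spec.element_counts``.  Paired
    bases are Watson-Crick complementary; unpaired bases are drawn
    uniformly.  Raises :class:`UnrealizableSpecError` when the counts
    violate the structural identities documented on the class or the
    length is too short.

    Returns ``(SequenceRecord, BasePairSet)``.
    """
    from .folding import BasePairSet  # deferred: avoid import cycle

    c = spec.counts()
    if spec.length < 1:
        raise UnrealizableSpecError("length must be >= 1")
    if c["H"] != c["L"]:
        raise UnrealizableSpecError(
            f"hairpin stems and loops must balance (H={c['H']}, L={c['L']})"
        )
    if c["D"] != c["I"] + c["G"] + c["M"]:
        raise UnrealizableSpecError(
            "each internal loop, bulge and multibranch loop needs exactly one "
            f"closing duplex helix (D={c['D']}, I+G+M={c['I'] + c['G'] + c['M']})"
        )
    if (c["I"] or c["G"] or c["M"]) and c["H"] == 0:
        raise UnrealizableSpecError("loops require at least one hairpin below them")
    if c["M"] and c["H"] < c["M"] + 1:
        raise UnrealizableSpecError(
            f"{c['M']} multibranch joins need at least {c['M'] + 1} hairpin branches"
        )
    roots = c["H"] - c["M"]
    if c["H"] == 0 and c["S"] != 1:
        raise UnrealizableSpecError(
            "a structure with no helices is a single exterior run (S must be 1)"
        )
    if c["S"] > roots + 1:
        raise UnrealizableSpecError(
            f"at most {roots + 1} exterior runs possible, {c['S']} requested"
        )
    need = _min_length(c)
    if spec.length < need:
        raise UnrealizableSpecError(
            f"length {spec.length} below minimum {need} for these counts"
        )
    pad = spec.length - need

    rng = np.random.default_rng(spec.seed)

    if c["H"] == 0:
        pairs: list[tuple[int, int]] = []
    else:
        # pad goes into the last exterior run, or the first hairpin loop
        # when there is no exterior run (neither changes element counts)
        loop0 = 3 + (pad if c["S"] == 0 else 0)
        units = [_Fragment(loop0 + 2, [(1, loop0 + 2)])]
        units.extend(_Fragment(5, [(1, 5)]) for _ in range(c["H"] - 1))
        # wrap internal loops and bulges round-robin over hairpin units
        for w in range(c["I"]):
            k = w % len(units)
            u = units[k]
            units[k] = _Fragment(
                u.length + 4, [(1, u.length + 4)] + u.shifted(2)
            )
        for w in range(c["G"]):
            k = w % len(units)
            u = units[k]
            units[k] = _Fragment(
                u.length + 3, [(1, u.length + 3)] + u.shifted(2)
            )
        # multibranch joins merge the first two top-level units
        for _ in range(c["M"]):
            u1, u2 = units[0], units[1]
            merged = _Fragment(
                u1.length + u2.length + 5,
                [(1, u1.length + u2.length + 5)]
                + u1.shifted(2)
                + u2.shifted(3 + u1.length),
            )
            units = [merged] + units[2:]
        # interleave exterior runs (1 nt each, pad added to the last one)
        run_lengths = [1] * c["S"]
        if c["S"]:
            run_lengths[-1] += pad
        pieces: list[tuple[str, _Fragment | int]] = []
        for k, u in enumerate(units):
            if k < len(run_lengths):
                pieces.append(("s", run_lengths[k]))
            pieces.append(("u", u))
        for k in range(len(units), len(run_lengths)):
            pieces.append(("s", run_lengths[k]))
        pos = 0
        pairs = []
        for kind, item in pieces:
            if kind == "s":
                pos += item  # type: ignore[operator]
            else:
                frag: _Fragment = item  # type: ignore[assignment]
                pairs.extend(frag.shifted(pos))
                pos += frag.length
        assert pos == spec.length, (pos, spec.length)

    bps = BasePairSet(pairs=frozenset(pairs), length=spec.length)
    seq = rng.choice(list(DNA_ALPHABET), size=spec.length)
    for i, j in pairs:
        seq[j - 1] = _WC[str(seq[i - 1])]
    record = SequenceRecord(
        id=f"planted{spec.seed}",
        sequence="".join(seq),
        origin="planted",
        segments=None,
    )
    return record, bps


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, origin: str = "aptamer") -> list[SequenceRecord]:
    """Read DNA records; lowercase input is uppercased with a warning."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(
                f"record {rec.id!r}: lowercase bases uppercased", stacklevel=2
            )
            seq = seq.upper()
        segments = None
        if seq.startswith(FLANK5) and seq.endswith(FLANK3):
            segments = ((1, 14), (15, len(seq) - 15), (len(seq) - 14, len(seq)))
        records.append(
            SequenceRecord(id=rec.id, sequence=seq, origin=origin, segments=segments)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.origin) for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")
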