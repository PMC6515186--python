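"""Secondary-structure-element decomposition and family assignment.

A pseudoknot-free base-pair set decomposes uniquely into seven element
kinds via the standard loop taxonomy:

====  =========================  =========================================
code  element                    rule
====  =========================  =========================================
S     single-stranded segment    maximal unpaired run exterior to all pairs
H     hairpin stem               helix directly closing a hairpin loop
L     hairpin loop               loop closed by 1 pair, all-unpaired inside
I     internal loop              2 closing pairs, unpaired on both sides
G     bulge                      2 closing pairs, unpaired on one side only
D     duplex                     any helix that is not a hairpin stem
M     multi-branched loop        loop with >= 3 closing pairs
====  =========================  =========================================

One element = one feature: a helix counts once (both strands), an internal
loop once (both unpaired stretches), a multibranch loop once (all its
stretches).  Replacing each base with its element's letter yields the
69-letter secondary structure string (SS$) used by the positional scoring
and alignment stages.  Structures sharing the exact same 7-long element
count vector — ignoring element length, position and base content — form a
secondary structure family (SSF).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .folding import BasePairSet

__all__ = [
    "SSE_ALPHABET",
    "Element",
    "StructureAnnotation",
    "SSFamily",
    "SSFCatalog",
    "annotate_structure",
    "to_ss_string",
    "assign_families",
    "annotation_table",
]

#: canonical element order used for count vectors and matrices
SSE_ALPHABET = "SHLIGDM"
SSE_INDEX = {k: i for i, k in enumerate(SSE_ALPHABET)}

SSE_NAMES = {
    "S": "single-stranded segment",
    "H": "hairpin stem",
    "L": "hairpin loop",
    "I": "internal loop",
    "G": "bulge",
    "D": "duplex",
    "M": "multi-branched loop",
}


@dataclass(frozen=True)
class Element:
    """One element occurrence: kind plus the 1-based base spans it covers."""

    kind: str
    spans: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.spans) if self.spans else 0

    @property
    def n_bases(self) -> int:
        return sum(e - s + 1 for s, e in self.spans)


@dataclass(frozen=True)
class StructureAnnotation:
    """Per-base SSE letters plus the element list and 7-long count vector."""

    ss_string: str
    elements: tuple[Element, ...]
    count_vector: tuple[int, ...]  # counts in SSE_ALPHABET order

    @property
    def counts(self) -> dict[str, int]:
        return dict(zip(SSE_ALPHABET, self.count_vector))

    def __len__(self) -> int:
        return len(self.ss_string)


def _helices(pairs: BasePairSet) -> list[list[tuple[int, int]]]:
    """Maximal runs of contiguously stacked pairs, outermost pair first."""
    pset = pairs.pairs
    helices = []
    for i, j in sorted(pset):
        if (i - 1, j + 1) in pset:
            continue  # not the outermost pair of its helix
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pset:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        helices.append(run)
    return helices


def _direct_children(
    a: int, b: int, partner: Mapping[int, int]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Top-level pairs and maximal unpaired runs strictly inside (a, b)."""
    children = []
    runs = []
    p = a + 1
    run_start = None
    while p < b:
        q = partner.get(p)
        if q is None:
            if run_start is None:
                run_start = p
            p += 1
        else:
            if run_start is not None:
                runs.append((run_start, p - 1))
                run_start = None
            children.append((p, q))
            p = q + 1
    if run_start is not None:
        runs.append((run_start, b - 1))
    return children, runs


def annotate_structure(pairs: BasePairSet) -> StructureAnnotation:
    """Decompose a base-pair set into elements and emit the SS$ string.

    Every base receives exactly one letter; paired bases carry H or D,
    unpaired bases S, L, I, G or M.  A loop with no unpaired bases (a
    zero-length multibranch junction) still counts as an element but
    contributes no letters.
    """
    n = pairs.length
    partner = pairs.partner()
    letters = [""] * (n + 1)  # 1-based
    elements: list[Element] = []

    helix_runs = _helices(pairs)
    helix_letter: dict[int, str] = {}  # keyed by outermost i of the helix

    for run in helix_runs:
        inner_i, inner_j = run[-1]
        children, unpaired = _direct_children(inner_i, inner_j, partner)
        if not children:
            kind = "L"
        elif len(children) == 1:
            (ci, cj) = children[0]
            left = ci - inner_i - 1
            right = inner_j - cj - 1
            assert left or right, "contiguous stacking inside a maximal helix"
            kind = "I" if (left and right) else "G"
        else:
            kind = "M"
        elements.append(Element(kind=kind, spans=tuple(unpaired)))
        for s, e in unpaired:
            for p in range(s, e + 1):
                letters[p] = kind
        helix_letter[run[0][0]] = "H" if kind == "L" else "D"

    for run in helix_runs:
        hl = helix_letter[run[0][0]]
        i0, j0 = run[0]
        ik, jk = run[-1]
        elements.append(Element(kind=hl, spans=((i0, ik), (jk, j0))))
        for i, j in run:
            letters[i] = hl
            letters[j] = hl

    # exterior single-stranded runs
    exterior_children, exterior_runs = _direct_children(0, n + 1, partner)
    for s, e in exterior_runs:
        elements.append(Element(kind="S", spans=((s, e),)))
        for p in range(s, e + 1):
            letters[p] = "S"

    elements.sort(key=lambda el: (el.start, el.kind))
    counts = [0] * len(SSE_ALPHABET)
    for el in elements:
        counts[SSE_INDEX[el.kind]] += 1
    ss = "".join(letters[1:])
    assert len(ss) == n and "" not in letters[1:]
    return StructureAnnotation(
        ss_string=ss, elements=tuple(elements), count_vector=tuple(counts)
    )


def to_ss_string(ann: StructureAnnotation) -> str:
    """The per-base element-letter string (SS$) of an annotation."""
    return ann.ss_string


@dataclass(frozen=True)
class SSFamily:
    id: str
    count_vector: tuple[int, ...]
    members: tuple[str, ...]


@dataclass(frozen=True)
class SSFCatalog:
    """Families (>= 2 members sharing a count vector) plus singletons."""

    families: tuple[SSFamily, ...]
    unassigned: tuple[str, ...]

    def family_of(self, label: str) -> str | None:
        for fam in self.families:
            if label in fam.members:
                return fam.id
        return None


def assign_families(
    annotations: Mapping[str, StructureAnnotation]
    | Iterable[tuple[str, StructureAnnotation]],
) -> SSFCatalog:
    """Group structures by identical element-count vectors.

    Element length, base position and base content are ignored — only the
    7-long count vector matters.  Vectors observed once go to
    ``unassigned``.  The grouping is invariant under input order: families
    are sorted by descending size then count vector, and labelled SSF1..n.
    """
    items = list(annotations.items()) if isinstance(annotations, Mapping) else list(annotations)
    if not items:
        raise ValueError("no annotations to group")
    groups: dict[tuple[int, ...], list[str]] = defaultdict(list)
    for label, ann in items:
        groups[ann.count_vector].append(label)
    fams = []
    unassigned = []
    for vec, labels in groups.items():
        if len(labels) >= 2:
            fams.append((vec, tuple(sorted(labels))))
        else:
            unassigned.extend(labels)
    fams.sort(key=lambda t: (-len(t[1]), t[0]))
    families = tuple(
        SSFamily(id=f"SSF{i + 1}", count_vector=vec, members=members)
        for i, (vec, members) in enumerate(fams)
    )
    return SSFCatalog(families=families, unassigned=tuple(sorted(unassigned)))


def annotation_table(
    annotations: Mapping[str, StructureAnnotation],
    catalog: SSFCatalog | None = None,
) -> pd.DataFrame:
    """One row per structure: label, SS$, 7 count columns, family id."""
    if catalog is None:
        catalog = assign_families(annotations)
    rows = []
    for label, ann in annotations.items():
        row = {"label": label, "ss_string": ann.ss_string}
        row.update({k: c for k, c in zip(SSE_ALPHABET, ann.count_vector)})
        row["family"] = catalog.family_of(label) or ""
        rows.append(row)
    return pd.DataFrame(rows)
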