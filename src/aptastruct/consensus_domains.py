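"""Consensus domains, gap regions and non-gap regions of an MSS$A.

Alignment columns are classified with ties counting toward the threshold
(">= 50%"): a column is a *gap* column when at least half its characters
are gaps; otherwise it is a *consensus* column when a single element
letter accounts for at least half the rows (gaps included in the
denominator); anything else is *non-gap*.  Maximal runs of one class form
regions, numbered 5'->3' within each kind; the consensus letters of a
domain's columns concatenate into its structure-string identity.

Domain statistics follow the membership rule: a sequence *contains* a
domain when its row matches the column consensus letter in at least half
of the domain's columns.  Projection removes gaps row by row, mapping each
domain back onto ungapped base coordinates to give per-base inclusion
ratios, inter-domain distances (d_(n,n+1), d_prior, d_next) and the mean
number of bases lost from a domain's interior (domain loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mssa_alignment import GAP, MultipleAlignment

__all__ = [
    "ColumnClass",
    "DomainRegion",
    "DomainStats",
    "ProjectedDomainMap",
    "classify_columns",
    "segment_regions",
    "domain_stats",
    "project_domains",
]

#: fixed primer-binding segments of the standard 69-nt design (1-based)
STANDARD_FIXED_SPANS = ((1, 14), (55, 69))


@dataclass(frozen=True)
class ColumnClass:
    """Per-column classification of an alignment."""

    classes: tuple[str, ...]  # 'consensus' | 'gap' | 'nongap'
    consensus_letters: tuple[str | None, ...]
    consensus_fractions: tuple[float, ...]


@dataclass(frozen=True)
class DomainRegion:
    kind: str  # 'consensus' | 'gap' | 'nongap'
    start: int  # 1-based column span, inclusive
    stop: int
    index: int  # numbered 5'->3' within kind (domain 1, gap 1, ...)
    ss_identity: str = ""  # consensus letters (consensus kind only)

    @property
    def name(self) -> str:
        stem = {"consensus": "domain", "gap": "gap", "nongap": "nongap"}[self.kind]
        return f"{stem}{self.index}"

    @property
    def columns(self) -> range:
        return range(self.start, self.stop + 1)


@dataclass(frozen=True)
class DomainStats:
    per_region: pd.DataFrame
    domains_per_sequence: float
    pct_ss_in_domains: float
    membership: pd.DataFrame  # rows x consensus domains, boolean


@dataclass(frozen=True)
class ProjectedDomainMap:
    spans: pd.DataFrame  # one row per (sequence, domain): base span + loss
    inclusion: pd.DataFrame  # domains x base positions, inclusion ratios
    distances: pd.DataFrame  # per domain: d_to_next, d_prior, d_next, loss


def classify_columns(
    aln: MultipleAlignment,
    gap_threshold: float = 0.5,
    consensus_threshold: float = 0.5,
) -> ColumnClass:
    if not aln.rows:
        raise ValueError("empty alignment")
    rows = list(aln.rows.values())
    n = len(rows)
    classes, letters, fractions = [], [], []
    for j in range(aln.n_columns):
        col = [r[j] for r in rows]
        gap_frac = col.count(GAP) / n
        if gap_frac >= gap_threshold:
            classes.append("gap")
            letters.append(None)
            fractions.append(gap_frac)
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        # deterministic tie-break: higher count, then alphabetical letter
        letter, cnt = min(counts.items(), key=lambda t: (-t[1], t[0]))
        frac = cnt / n  # gaps stay in the denominator
        if frac >= consensus_threshold:
            classes.append("consensus")
            letters.append(letter)
            fractions.append(frac)
        else:
            classes.append("nongap")
            letters.append(None)
            fractions.append(frac)
    return ColumnClass(
        classes=tuple(classes),
        consensus_letters=tuple(letters),
        consensus_fractions=tuple(fractions),
    )


def segment_regions(cc: ColumnClass) -> list[DomainRegion]:
    """Maximal same-class runs, numbered 5'->3' within each kind."""
    regions: list[DomainRegion] = []
    counters = {"consensus": 0, "gap": 0, "nongap": 0}
    j = 0
    ncol = len(cc.classes)
    while j < ncol:
        kind = cc.classes[j]
        start = j
        while j < ncol and cc.classes[j] == kind:
            j += 1
        counters[kind] += 1
        identity = ""
        if kind == "consensus":
            identity = "".join(
                cc.consensus_letters[x] or "" for x in range(start, j)
            )
        regions.append(
            DomainRegion(
                kind=kind,
                start=start + 1,
                stop=j,
                index=counters[kind],
                ss_identity=identity,
            )
        )
    return regions


def _consensus_regions(regions: Sequence[DomainRegion]) -> list[DomainRegion]:
    return [r for r in regions if r.kind == "consensus"]


def _row_membership(
    row: str, region: DomainRegion, cc: ColumnClass, threshold: float
) -> bool:
    cols = list(region.columns)
    hits = sum(
        1 for c in cols if row[c - 1] == cc.consensus_letters[c - 1]
    )
    return hits / len(cols) >= threshold


def _base_positions(row: str) -> list[int]:
    """Ungapped base position of each column (0 where the row has a gap)."""
    out = []
    p = 0
    for ch in row:
        if ch == GAP:
            out.append(0)
        else:
            p += 1
            out.append(p)
    return out


def domain_stats(
    aln: MultipleAlignment,
    regions: Sequence[DomainRegion],
    cc: ColumnClass | None = None,
    membership_threshold: float = 0.5,
    fixed_spans: Sequence[tuple[int, int]] = STANDARD_FIXED_SPANS,
) -> DomainStats:
    """Per-region and per-population statistics of an alignment.

    Per consensus domain: mean +/- SD of per-sequence projected length
    (over member rows), mean column consensus (*conserved*), fraction of
    rows containing the domain (*frequency*) and the mean fraction of a
    member row's domain characters falling in the fixed-base segments
    (*fraction fixed base*).  Gap/non-gap region lengths are averaged over
    all rows.  Population statistics: mean number of domains containing a
    row, and the mean percentage of a row's (ungapped) characters lying in
    consensus-domain columns.
    """
    if cc is None:
        cc = classify_columns(aln)
    labels = list(aln.rows)
    cons = _consensus_regions(regions)
    member = pd.DataFrame(
        {
            r.name: [
                _row_membership(aln.rows[l], r, cc, membership_threshold)
                for l in labels
            ]
            for r in cons
        },
        index=labels,
        dtype=bool,
    ) if cons else pd.DataFrame(index=labels)

    fixed = set()
    for a, b in fixed_spans:
        fixed.update(range(a, b + 1))

    rows_stats = []
    for r in regions:
        cols = list(r.columns)
        if r.kind == "consensus":
            members = [l for l in labels if member.loc[l, r.name]]
        else:
            members = labels
        lengths = [
            sum(1 for c in cols if aln.rows[l][c - 1] != GAP) for l in members
        ]
        entry = {
            "region": r.name,
            "kind": r.kind,
            "start_col": r.start,
            "stop_col": r.stop,
            "ss_identity": r.ss_identity,
            "mean_length": float(np.mean(lengths)) if lengths else 0.0,
            "sd_length": float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0,
        }
        if r.kind == "consensus":
            entry["conserved"] = float(
                np.mean([cc.consensus_fractions[c - 1] for c in cols])
            )
            entry["frequency"] = (
                float(member[r.name].mean()) if labels else 0.0
            )
            fracs = []
            for l in members:
                bases = _base_positions(aln.rows[l])
                dom_bases = [bases[c - 1] for c in cols if bases[c - 1]]
                if dom_bases:
                    fracs.append(
                        sum(1 for p in dom_bases if p in fixed) / len(dom_bases)
                    )
            entry["fraction_fixed_base"] = float(np.mean(fracs)) if fracs else np.nan
        rows_stats.append(entry)
    per_region = pd.DataFrame(rows_stats)

    if cons:
        domains_per_sequence = float(member.sum(axis=1).mean())
        cons_cols = {c for r in cons for c in r.columns}
        pcts = []
        for l in labels:
            row = aln.rows[l]
            total = sum(1 for ch in row if ch != GAP)
            inside = sum(
                1 for c in cons_cols if row[c - 1] != GAP
            )
            pcts.append(100.0 * inside / total if total else 0.0)
        pct_ss = float(np.mean(pcts))
    else:
        domains_per_sequence = 0.0
        pct_ss = 0.0
    return DomainStats(
        per_region=per_region,
        domains_per_sequence=domains_per_sequence,
        pct_ss_in_domains=pct_ss,
        membership=member,
    )


def project_domains(
    aln: MultipleAlignment,
    regions: Sequence[DomainRegion],
    max_base: int | None = None,
) -> ProjectedDomainMap:
    """Map consensus domains onto ungapped base coordinates, row by row.

    A row lacking any non-gap character in a domain contributes a null
    span (reported as NaN).  Distances are in bases between projected
    spans; ``d_prior``/``d_next`` fall back to the strand ends when no
    neighboring domain exists.  ``domain_loss`` counts domain columns
    where the row carries a gap.
    """
    cons = _consensus_regions(regions)
    if not cons:
        raise ValueError("no consensus regions to project")
    labels = list(aln.rows)
    span_rows = []
    row_lengths = {}
    for l in labels:
        row = aln.rows[l]
        bases = _base_positions(row)
        row_lengths[l] = max(bases)
        for r in cons:
            cols = list(r.columns)
            dom_bases = [bases[c - 1] for c in cols if bases[c - 1]]
            loss = sum(1 for c in cols if bases[c - 1] == 0)
            if dom_bases:
                span_rows.append(
                    {
                        "label": l,
                        "domain": r.name,
                        "base_start": min(dom_bases),
                        "base_stop": max(dom_bases),
                        "domain_loss": loss,
                    }
                )
            else:
                span_rows.append(
                    {
                        "label": l,
                        "domain": r.name,
                        "base_start": np.nan,
                        "base_stop": np.nan,
                        "domain_loss": loss,
                    }
                )
    spans = pd.DataFrame(span_rows)

    nbase = max_base or max(row_lengths.values())
    inclusion = pd.DataFrame(
        0.0, index=[r.name for r in cons], columns=range(1, nbase + 1)
    )
    for r in cons:
        sub = spans[(spans["domain"] == r.name) & spans["base_start"].notna()]
        for _, rec in sub.iterrows():
            a, b = int(rec["base_start"]), int(rec["base_stop"])
            inclusion.loc[r.name, a:b] += 1.0
        inclusion.loc[r.name] /= len(labels)

    by_key = {(rec["label"], rec["domain"]): rec for rec in span_rows}
    dist_rows = []
    for k, r in enumerate(cons):
        d_next_vals, d_prior_vals, d_gap_vals, losses = [], [], [], []
        for l in labels:
            rec = by_key[(l, r.name)]
            losses.append(rec["domain_loss"])
            if np.isnan(rec["base_start"]):
                continue
            a, b = rec["base_start"], rec["base_stop"]
            nxt = by_key[(l, cons[k + 1].name)] if k + 1 < len(cons) else None
            if nxt is not None and not np.isnan(nxt["base_start"]):
                d_gap_vals.append(nxt["base_start"] - b - 1)
                next_dist = nxt["base_start"] - b - 1
            else:
                next_dist = None
            prev_start = None
            if k > 0:
                prv = by_key[(l, cons[k - 1].name)]
                if not np.isnan(prv["base_stop"]):
                    prev_start = a - prv["base_stop"] - 1
            d_prior_vals.append(prev_start if prev_start is not None else a - 1)
            d_next_vals.append(
                next_dist if next_dist is not None else row_lengths[l] - b
            )
        dist_rows.append(
            {
                "domain": r.name,
                "d_to_next": float(np.mean(d_gap_vals)) if d_gap_vals else np.nan,
                "d_prior": float(np.mean(d_prior_vals)) if d_prior_vals else np.nan,
                "d_next": float(np.mean(d_next_vals)) if d_next_vals else np.nan,
                "domain_loss": float(np.mean(losses)) if losses else np.nan,
            }
        )
    distances = pd.DataFrame(dist_rows)
    return ProjectedDomainMap(spans=spans, inclusion=inclusion, distances=distances)
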