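"""Flank-matching classification of long amplicon reads.

Each junction of interest (the two wild-type cut sites, the two inversion
borders, and the fused deletion junction) is described by a pair of 16 bp
flanks whose inner edges sit ~30 bp either side of the double-strand break,
so the flanks are ~60 bp apart on an unedited molecule with the break
centred between them. A read matches a junction when its left flank is
followed by its right flank within a bounded gap: small deletions at the
break shrink the gap below the nominal spacing, and insertions of up to
``max_insert`` (default 80 bp) widen it. Matching is exact substring search
on both strands, mirroring a grep-style pattern scan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .locus import LocusPair, revcomp

WT_LEFT = "wt_left"
WT_RIGHT = "wt_right"
INV_LEFT = "inv_left"
INV_RIGHT = "inv_right"
DEL = "del"

READ_LABELS = ("wild_type", "inversion", "complete_inversion", "deletion", "other")


@dataclass(frozen=True)
class JunctionQuery:
    """One junction pattern: two flanks and the gap they may enclose."""

    label: str
    left_flank: str
    right_flank: str
    nominal_spacing_bp: int = 60
    min_insert: int = 0
    max_insert: int = 80

    def __post_init__(self) -> None:
        if len(self.left_flank) != len(self.right_flank):
            raise ValueError("flanks must have equal length")
        if not 0 <= self.min_insert <= self.max_insert:
            raise ValueError("require 0 <= min_insert <= max_insert")

    @property
    def max_gap(self) -> int:
        """Largest admissible inter-flank gap: nominal spacing + max insert."""
        return self.nominal_spacing_bp + self.max_insert

    def pattern(self) -> re.Pattern:
        return re.compile(
            re.escape(self.left_flank)
            + f"(.{{{self.min_insert},{self.max_gap}}}?)"
            + re.escape(self.right_flank)
        )


@lru_cache(maxsize=512)
def _compiled(query: JunctionQuery) -> re.Pattern:
    return query.pattern()


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    label: str
    matched: tuple[str, ...]
    signature: str


def build_queries(
    locus: LocusPair,
    flank_len: int = 16,
    spacing: int = 60,
    max_insert: int = 80,
) -> list[JunctionQuery]:
    """Derive the five junction queries from a locus.

    With 0-based split indices a < b for the two cuts and offset = spacing/2:
    L(c) is the flank ending ``offset`` bases left of cut c, R(c) the flank
    starting ``offset`` bases right of it. Wild-type junctions pair L and R of
    the same cut; the left inversion border pairs L(a) with the reverse
    complement of L(b) (the inverted segment begins with the reverse
    complement of the sequence just inside cut b); the right border pairs the
    reverse complement of R(a) with R(b); the deletion junction fuses L(a)
    with R(b).
    """
    off = spacing // 2
    seg = locus.ref_segment
    a, b = locus.left_cut, locus.right_cut
    for c in (a, b):
        if c - off - flank_len < 0 or c + off + flank_len > len(seg):
            raise ValueError(
                f"cut at {c} is within flank reach of the segment end; "
                "extend ref_segment margins"
            )

    def L(c: int) -> str:
        return seg[c - off - flank_len : c - off]

    def R(c: int) -> str:
        return seg[c + off : c + off + flank_len]

    common = dict(nominal_spacing_bp=2 * off, max_insert=max_insert)
    return [
        JunctionQuery(WT_LEFT, L(a), R(a), **common),
        JunctionQuery(WT_RIGHT, L(b), R(b), **common),
        JunctionQuery(INV_LEFT, L(a), revcomp(L(b)), **common),
        JunctionQuery(INV_RIGHT, revcomp(R(a)), R(b), **common),
        JunctionQuery(DEL, L(a), R(b), **common),
    ]


def _label_from_matches(matched: set[str]) -> str:
    inv = matched & {INV_LEFT, INV_RIGHT}
    if inv and DEL in matched:
        return "other"  # chimeric inversion+deletion signal
    if len(inv) == 2:
        return "complete_inversion"
    if len(inv) == 1:
        return "inversion"
    if DEL in matched:
        return "deletion"
    if {WT_LEFT, WT_RIGHT} <= matched:
        return "wild_type"
    return "other"


def scan_read(
    read, queries: list[JunctionQuery], read_id: str | None = None
) -> ReadCall:
    """Classify one read by scanning both strands for every junction query.

    Label precedence: complete_inversion > inversion > deletion > wild_type >
    other; reads matching both inversion and deletion junctions are chimeric
    and labelled other. The signature concatenates each matched junction's
    inter-flank sequence (strand-canonicalised), so identical repair products
    deduplicate regardless of read orientation.
    """
    seq = getattr(read, "seq", read).upper()
    rid = read_id if read_id is not None else getattr(read, "read_id", "")
    rc = revcomp(seq)
    matched: dict[str, str] = {}
    for q in queries:
        pat = _compiled(q)
        gaps = [m.group(1) for s in (seq, rc) for m in [pat.search(s)] if m]
        if gaps:
            # canonical gap: lexicographic min over strands, orientation-stable
            matched[q.label] = min(gaps)
    label = _label_from_matches(set(matched))
    sig_labels = sorted(k for k in matched if k in (INV_LEFT, INV_RIGHT, DEL))
    signature = ";".join(f"{k}:{matched[k]}" for k in sig_labels)
    return ReadCall(read_id=rid, label=label, matched=tuple(sorted(matched)), signature=signature)


@dataclass
class ReadsetSummary:
    n_reads: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    unique_events: pd.DataFrame  # columns: label, signature, count
    deletion_inversion_ratio: float | None
    calls: list[ReadCall] = field(repr=False, default_factory=list)


def classify_readset(reads, queries: list[JunctionQuery]) -> ReadsetSummary:
    """Classify a read set and summarise label counts and unique events.

    Unique events are distinct junction signatures among rearranged reads —
    two reads carrying byte-identical junction inserts count as one event.
    The deletion:inversion ratio uses all inversion-junction reads (single
    and complete) and is None (flagged) when no inversion reads exist.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("empty read set")
    calls = [scan_read(r, queries, read_id=getattr(r, "read_id", str(i)))
             for i, r in enumerate(reads)]
    counts = {lab: 0 for lab in READ_LABELS}
    for c in calls:
        counts[c.label] += 1
    n = len(calls)
    freqs = {lab: counts[lab] / n for lab in READ_LABELS}
    ev_rows = [
        (c.label, c.signature)
        for c in calls
        if c.label in ("inversion", "complete_inversion", "deletion")
    ]
    if ev_rows:
        unique = (
            pd.DataFrame(ev_rows, columns=["label", "signature"])
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["label", "count"], ascending=[True, False])
            .reset_index(drop=True)
        )
    else:
        unique = pd.DataFrame(columns=["label", "signature", "count"])
    n_inv = counts["inversion"] + counts["complete_inversion"]
    ratio = counts["deletion"] / n_inv if n_inv > 0 else None
    return ReadsetSummary(
        n_reads=n,
        counts=counts,
        frequencies=freqs,
        unique_events=unique,
        deletion_inversion_ratio=ratio,
        calls=calls,
    )
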