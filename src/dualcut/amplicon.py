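"""Per-site indel quantification from short amplicon reads.

Reads are globally aligned to the reference amplicon with affine gap
penalties; a read counts as mutated when it carries at least one insertion
or deletion whose reference span intersects the cut window — the two
nucleotides flanking the blunt Cas9 cut, extended by a fixed buffer (default
4 bp) on either side. Substitutions never count. Negative-control read sets
sequenced from unedited material are used to strip event classes that are as
frequent without editing (pre-existing variants, PCR/sequencing artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import Align


@dataclass(frozen=True)
class IndelCallConfig:
    """Alignment and windowing settings for indel calling.

    cut_window_nt : width of the core cut window (2 = the nucleotides either
        side of the blunt cut).
    cut_buffer_bp : extension of the window on both sides; an indel qualifies
        when its reference span intersects
        [cut_pos - buffer, cut_pos + window - 1 + buffer].
    min_reads : QC floor; below it the call is flagged.
    control_threshold : an event class is removed by control subtraction when
        its pooled control frequency >= threshold * its sample frequency.
    min_read_len_frac : reads shorter than this fraction of the reference are
        discarded before alignment.
    """

    cut_window_nt: int = 2
    cut_buffer_bp: int = 4
    min_reads: int = 100
    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    control_threshold: float = 0.5
    min_read_len_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.cut_window_nt < 1:
            raise ValueError("cut_window_nt must be >= 1")
        if self.cut_buffer_bp < 0:
            raise ValueError("cut_buffer_bp must be >= 0")
        if self.control_threshold <= 0:
            raise ValueError("control_threshold must be positive")


class AlignmentEvent(NamedTuple):
    """One alignment difference in reference coordinates (1-based).

    For deletions ``position`` is the first deleted reference base and
    ``size`` the number of deleted bases; for insertions ``position`` is the
    reference base after which ``size`` bases are inserted; substitutions
    have size 1.
    """

    kind: str  # 'sub' | 'ins' | 'del'
    position: int
    size: int


def _aligner(cfg: IndelCallConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


def align_to_reference(
    read: str, ref_amplicon: str, cfg: IndelCallConfig | None = None
) -> list[AlignmentEvent] | None:
    """Globally align a read to the reference amplicon and list differences.

    Returns None (discarded-read signal) when the read is shorter than
    ``min_read_len_frac`` of the reference. The first optimal alignment
    reported by the aligner is used, making event coordinates deterministic.
    """
    cfg = cfg or IndelCallConfig()
    read = str(getattr(read, "seq", read)).upper()
    ref = str(ref_amplicon).upper()
    if not read or not ref:
        raise ValueError("read and reference must be non-empty")
    if len(read) < cfg.min_read_len_frac * len(ref):
        return None
    alignment = _aligner(cfg).align(ref, read)[0]
    ref_blocks, read_blocks = alignment.aligned
    events: list[AlignmentEvent] = []
    prev_ref_end = prev_read_end = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        if rs > prev_ref_end:
            events.append(AlignmentEvent("del", prev_ref_end + 1, rs - prev_ref_end))
        if qs > prev_read_end:
            events.append(AlignmentEvent("ins", rs, qs - prev_read_end))
        for k in range(re_ - rs):
            if ref[rs + k] != read[qs + k]:
                events.append(AlignmentEvent("sub", rs + k + 1, 1))
        prev_ref_end, prev_read_end = re_, qe
    if len(ref) > prev_ref_end:
        events.append(AlignmentEvent("del", prev_ref_end + 1, len(ref) - prev_ref_end))
    if len(read) > prev_read_end:
        events.append(AlignmentEvent("ins", len(ref), len(read) - prev_read_end))
    events.sort(key=lambda e: (e.position, e.kind))
    return events


def _window(cut_pos: int, cfg: IndelCallConfig) -> tuple[int, int]:
    lo = cut_pos - cfg.cut_buffer_bp
    hi = cut_pos + cfg.cut_window_nt - 1 + cfg.cut_buffer_bp
    return lo, hi


def _qualifies(event: AlignmentEvent, lo: int, hi: int) -> bool:
    if event.kind == "del":
        return event.position <= hi and event.position + event.size - 1 >= lo
    if event.kind == "ins":
        # insertion sits between position and position+1
        return lo - 1 <= event.position <= hi
    return False  # substitutions never count


@dataclass
class SiteMutationCall:
    """Indel-based mutation call for one cut site."""

    site_id: str
    n_reads: int
    n_discarded: int
    n_mutated: int
    raw_frequency: float
    control_adjusted_frequency: float
    events: pd.DataFrame  # columns: kind, position, size, count
    qc_fail: bool
    flags: list[str] = field(default_factory=list)
    read_events: list[frozenset] = field(default_factory=list, repr=False)


def site_mutation_frequency(
    reads: Iterable,
    ref_amplicon: str,
    cut_pos: int,
    cfg: IndelCallConfig | None = None,
    site_id: str = "site",
) -> SiteMutationCall:
    """Fraction of reads carrying a qualifying indel at the cut window.

    ``cut_pos`` is the 1-based reference position immediately 5' of the blunt
    cut. Identical read sequences are aligned once and cached, which keeps
    deep amplicon sets fast (most reads are exact duplicates of a few
    alleles).
    """
    cfg = cfg or IndelCallConfig()
    if not 1 <= cut_pos < len(ref_amplicon):
        raise ValueError("cut_pos must lie inside the reference amplicon")
    seqs = [str(getattr(r, "seq", r)).upper() for r in reads]
    if not seqs:
        raise ValueError("need at least one read")
    lo, hi = _window(cut_pos, cfg)
    cache: dict[str, frozenset | None] = {}
    read_events: list[frozenset] = []
    n_discarded = 0
    event_counts: dict[AlignmentEvent, int] = {}
    for seq in seqs:
        if seq not in cache:
            events = align_to_reference(seq, ref_amplicon, cfg)
            if events is None:
                cache[seq] = None
            else:
                cache[seq] = frozenset(e for e in events if _qualifies(e, lo, hi))
        qual = cache[seq]
        if qual is None:
            n_discarded += 1
            continue
        read_events.append(qual)
        for e in qual:
            event_counts[e] = event_counts.get(e, 0) + 1
    n_reads = len(read_events)
    n_mutated = sum(1 for q in read_events if q)
    raw = n_mutated / n_reads if n_reads else 0.0
    table = pd.DataFrame(
        [(e.kind, e.position, e.size, c) for e, c in sorted(event_counts.items())],
        columns=["kind", "position", "size", "count"],
    )
    return SiteMutationCall(
        site_id=site_id,
        n_reads=n_reads,
        n_discarded=n_discarded,
        n_mutated=n_mutated,
        raw_frequency=raw,
        control_adjusted_frequency=raw,
        events=table,
        qc_fail=n_reads < cfg.min_reads,
        read_events=read_events,
    )


def control_subtract(
    sample: SiteMutationCall,
    controls: list[SiteMutationCall],
    cfg: IndelCallConfig | None = None,
) -> SiteMutationCall:
    """Remove event classes explained by the negative controls.

    Event classes (kind, position, size) whose pooled control frequency is at
    least ``control_threshold`` times their sample frequency are treated as
    background and dropped; the mutation frequency is then recomputed over
    reads that retain at least one qualifying event. The result is bounded in
    [0, 1] by construction.
    """
    cfg = cfg or IndelCallConfig()
    if not controls:
        return replace(sample, flags=sample.flags + ["no_controls"])
    ctrl_reads = sum(c.n_reads for c in controls)
    if ctrl_reads == 0:
        return replace(sample, flags=sample.flags + ["empty_controls"])
    ctrl_counts: dict[tuple, int] = {}
    for c in controls:
        for kind, pos, size, count in c.events.itertuples(index=False):
            key = (kind, int(pos), int(size))
            ctrl_counts[key] = ctrl_counts.get(key, 0) + int(count)
    removed: set[AlignmentEvent] = set()
    for kind, pos, size, count in sample.events.itertuples(index=False):
        ev = AlignmentEvent(kind, int(pos), int(size))
        sample_freq = count / sample.n_reads
        ctrl_freq = ctrl_counts.get((kind, int(pos), int(size)), 0) / ctrl_reads
        if sample_freq > 0 and ctrl_freq >= cfg.control_threshold * sample_freq:
            removed.add(ev)
    kept_reads = [q - removed for q in sample.read_events]
    n_mutated = sum(1 for q in kept_reads if q)
    adjusted = min(max(n_mutated / sample.n_reads, 0.0), 1.0) if sample.n_reads else 0.0
    events = sample.events[
        ~sample.events.apply(
            lambda r: AlignmentEvent(r["kind"], int(r["position"]), int(r["size"])) in removed,
            axis=1,
        )
    ].reset_index(drop=True) if len(sample.events) else sample.events
    return replace(
        sample,
        control_adjusted_frequency=adjusted,
        events=events,
        read_events=kept_reads,
        flags=sample.flags + ([f"removed_{len(removed)}_background_events"] if removed else []),
    )
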