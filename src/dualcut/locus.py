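"""Dual-cut locus description: two SpCas9 target sites on one chromosome.

Coordinates are 1-based throughout. A blunt Cas9 cut at ``cut_pos`` falls
between reference positions ``cut_pos`` and ``cut_pos + 1``, i.e. 3 bp 5' of
the PAM on the protospacer strand (between protospacer positions 17 and 18).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


@dataclass(frozen=True)
class GuideSite:
    """A 20-nt SpCas9 protospacer with its PAM and strand."""

    protospacer: str
    pam: str
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class LocusPair:
    """Two Cas9 cut sites on one chromosome.

    The 'fixed' site is the internal-reference gRNA target shared by every
    construct; the 'variable' site sets the size of the interval that can be
    inverted or deleted. ``ref_segment`` covers both sites with enough margin
    to extract junction flanks and amplicon windows.
    """

    chrom_name: str
    ref_segment: str
    fixed_cut_pos: int
    variable_cut_pos: int
    fixed_guide: GuideSite
    variable_guide: GuideSite

    def __post_init__(self) -> None:
        n = len(self.ref_segment)
        for name, pos in (("fixed", self.fixed_cut_pos), ("variable", self.variable_cut_pos)):
            if not 1 <= pos < n:
                raise ValueError(f"{name} cut position {pos} outside ref_segment (length {n})")
        if self.fixed_cut_pos == self.variable_cut_pos:
            raise ValueError("cut positions must be distinct")
        _check_guide(self.ref_segment, self.fixed_cut_pos, self.fixed_guide, "fixed")
        _check_guide(self.ref_segment, self.variable_cut_pos, self.variable_guide, "variable")

    @property
    def interval_bp(self) -> int:
        return abs(self.variable_cut_pos - self.fixed_cut_pos)

    @property
    def left_cut(self) -> int:
        """Leftmost (smaller-coordinate) cut position."""
        return min(self.fixed_cut_pos, self.variable_cut_pos)

    @property
    def right_cut(self) -> int:
        return max(self.fixed_cut_pos, self.variable_cut_pos)


def _check_guide(seg: str, cut_pos: int, guide: GuideSite, name: str) -> None:
    """Verify the protospacer/PAM arrangement implies a cut at cut_pos."""
    seg = seg.upper()
    if guide.strand == "+":
        s0 = cut_pos - 16  # 1-based protospacer start
        proto = seg[s0 - 1 : s0 + 19]
        pam = seg[s0 + 19 : s0 + 22]
    else:
        s0 = cut_pos - 2
        proto = revcomp(seg[s0 - 1 : s0 + 19])
        pam = revcomp(seg[s0 - 4 : s0 - 1])
    if proto != guide.protospacer.upper() or pam != guide.pam.upper():
        raise ValueError(
            f"{name} guide does not place its cut 3 bp 5' of the PAM at position {cut_pos}"
        )


def make_locus(
    interval_bp: int,
    margin: int = 200,
    seed: int = 0,
    chrom_name: str = "chr6",
) -> LocusPair:
    """Build a random locus with two plus-strand NGG sites ``interval_bp`` apart.

    The variable cut lands at position ``margin``, the fixed cut at
    ``margin + interval_bp``; ``margin`` bases of flank remain on either side.
    Used by the simulator and tests; real loci are loaded from JSON instead.
    """
    if interval_bp <= 0:
        raise ValueError("interval_bp must be positive")
    if margin < 60:
        raise ValueError("margin must leave room for flanks and amplicons (>= 60)")
    rng = np.random.default_rng(seed)
    length = interval_bp + 2 * margin
    seq = list(random_dna(length, rng))
    var_cut = margin
    fix_cut = margin + interval_bp
    for cut in (var_cut, fix_cut):
        # force an NGG PAM so the cut is 3 bp 5' of it (0-based: GG at cut+4, cut+5)
        seq[cut + 4] = "G"
        seq[cut + 5] = "G"
    seg = "".join(seq)

    def guide_at(cut: int) -> GuideSite:
        s0 = cut - 16
        return GuideSite(
            protospacer=seg[s0 - 1 : s0 + 19], pam=seg[s0 + 19 : s0 + 22], strand="+"
        )

    return LocusPair(
        chrom_name=chrom_name,
        ref_segment=seg,
        fixed_cut_pos=fix_cut,
        variable_cut_pos=var_cut,
        fixed_guide=guide_at(fix_cut),
        variable_guide=guide_at(var_cut),
    )
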