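"""Transcript coordinate maps: conversion between genomic (g.) and coding (c.) positions.

All genomic coordinates are internally 0-based, half-open, on the plus strand;
HGVS surfaces (g. and c. strings) are 1-based. A :class:`TranscriptMap` holds the
ordered exon structure of one transcript and supports strand-aware conversion of
coding positions with intronic offsets (``c.7310-19`` style) to genomic positions
and back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


class CoordinateError(ValueError):
    """Raised when a position cannot be mapped under the transcript model."""


@dataclass(frozen=True)
class CPos:
    """A coding-DNA position with an optional signed intronic offset.

    ``pos`` is the 1-based coding position of the anchoring exonic base;
    ``offset`` follows HGVS: positive counts into the downstream intron
    (donor side), negative into the upstream intron (acceptor side).
    """

    pos: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.pos)
        return f"{self.pos}{self.offset:+d}"


@dataclass
class TranscriptMap:
    """Exon structure of a transcript on a genomic sequence.

    Parameters
    ----------
    exons
        Genomic intervals (0-based, half-open, plus strand) listed in
        transcript order, i.e. 5'->3' along the mRNA.  For a minus-strand
        transcript the genomic coordinates therefore decrease along the list.
    strand
        ``"+"`` or ``"-"``.
    cds_start_t
        Transcript coordinate (0-based, in spliced-mRNA space) of coding
        position c.1.  Defaults to 0 (transcript starts at the CDS).
    """

    exons: Sequence[Tuple[int, int]]
    strand: str = "+"
    cds_start_t: int = 0

    _cum: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise CoordinateError("transcript map needs at least one exon")
        for s, e in self.exons:
            if e <= s:
                raise CoordinateError(f"empty or inverted exon interval ({s}, {e})")
        # non-overlap + ordering in transcript sense
        ordered = self.exons if self.strand == "+" else list(self.exons)[::-1]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise CoordinateError("exons overlap or are out of transcript order")
        cum = [0]
        for s, e in self.exons:
            cum.append(cum[-1] + (e - s))
        self._cum = cum

    # ------------------------------------------------------------------
    @property
    def length(self) -> int:
        return self._cum[-1]

    def t_to_g(self, tpos: int) -> int:
        """Spliced transcript coordinate (0-based) -> genomic 0-based plus-strand."""
        if not 0 <= tpos < self.length:
            raise CoordinateError(f"transcript position {tpos} outside transcript")
        for i, (s, e) in enumerate(self.exons):
            if tpos < self._cum[i + 1]:
                within = tpos - self._cum[i]
                if self.strand == "+":
                    return s + within
                return e - 1 - within
        raise AssertionError("unreachable")

    def g_to_t(self, gpos: int) -> Optional[int]:
        """Genomic 0-based -> transcript coordinate, or None if intronic."""
        for i, (s, e) in enumerate(self.exons):
            if s <= gpos < e:
                within = gpos - s if self.strand == "+" else e - 1 - gpos
                return self._cum[i] + within
        return None

    # ------------------------------------------------------------------
    def c_to_g(self, c: CPos) -> int:
        """Coding position (+ optional intronic offset) -> genomic 0-based position."""
        if c.pos < 1:
            raise CoordinateError("only coding positions >= 1 are supported")
        tpos = self.cds_start_t + c.pos - 1
        anchor = self.t_to_g(tpos)
        if c.offset == 0:
            return anchor
        # positive offsets run downstream in transcript sense, negative upstream
        if self.strand == "+":
            return anchor + c.offset
        return anchor - c.offset

    def g_to_c(self, gpos: int) -> CPos:
        """Genomic 0-based position -> coding position with HGVS intronic offset.

        Intronic positions anchor to the nearer exon boundary (HGVS convention:
        the 5' half of an intron is numbered ``+`` off the upstream exon, the
        3' half ``-`` off the downstream exon).
        """
        t = self.g_to_t(gpos)
        if t is not None:
            c = t - self.cds_start_t + 1
            if c < 1:
                raise CoordinateError("position upstream of CDS start is unsupported")
            return CPos(c)
        # intronic: find flanking exons in transcript order
        for i in range(len(self.exons) - 1):
            up = self.exons[i]
            down = self.exons[i + 1]
            if self.strand == "+":
                lo, hi = up[1], down[0]
                if lo <= gpos < hi:
                    d_up = gpos - up[1] + 1          # bases past the donor
                    d_down = down[0] - gpos          # bases before the acceptor
                    if d_up <= d_down:
                        return CPos(self._cum[i + 1] - self.cds_start_t, d_up)
                    return CPos(self._cum[i + 1] + 1 - self.cds_start_t, -d_down)
            else:
                lo, hi = down[1], up[0]
                if lo <= gpos < hi:
                    d_up = up[0] - gpos
                    d_down = gpos - down[1] + 1
                    if d_up <= d_down:
                        return CPos(self._cum[i + 1] - self.cds_start_t, d_up)
                    return CPos(self._cum[i + 1] + 1 - self.cds_start_t, -d_down)
        raise CoordinateError(f"genomic position {gpos} outside the transcript span")

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "exons": [list(x) for x in self.exons],
                "strand": self.strand,
                "cds_start_t": self.cds_start_t,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TranscriptMap":
        d = json.loads(text)
        return cls(
            exons=[tuple(x) for x in d["exons"]],
            strand=d["strand"],
            cds_start_t=d.get("cds_start_t", 0),
        )
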