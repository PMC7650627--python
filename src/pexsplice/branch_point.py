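"""Branch-point candidate search restricted to the AG-dinucleotide exclusion zone.

The functional branch point (BP) adenine lies in the AG exclusion zone
(AGEZ): the AG-free stretch immediately upstream of the 3' splice site.
Candidates are scored with a position weight matrix over a 7-mer whose
sixth position is the BP adenine (TACTAAC-style register), and two derived
features are reported: the distance of the BP adenine to the 3' ss, and the
pyrimidine content of the tract between the BP and the 3' ss.

The published BP predictor the field commonly uses is a trained SVM whose
weights are not recoverable from its description; this module is a PWM
surrogate with the same AGEZ restriction, best-candidate rule and derived
features, trainable from any user-supplied heptamer set.

Offsets are negative positions relative to the 3' ss: position -1 is the
last intronic base (the G of the terminal AG), -3 the first position
upstream of that AG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .consensus_motif import PWM

#: BP adenine register within the scored heptamer (0-based index 5 = 6th base)
BP_POS_IN_HEPTAMER = 5


class BranchPointError(ValueError):
    pass


@dataclass
class BPResult:
    bp_offset: int  # negative offset of the BP adenine from the 3' ss
    score: float  # PWM log2-odds, bits
    distance: int  # |bp_offset|
    ppt_fraction: float  # pyrimidine fraction of (bp_offset, -3]
    agez: Tuple[int, int]  # inclusive interval [-d, -3]


def compute_agez(
    intron_tail: str, search_limit: Optional[int] = None
) -> Tuple[int, int]:
    """Maximal AG-free interval ``[-d, -3]`` upstream of the 3' ss.

    ``intron_tail`` is the 3' end of the intron and must end with the splice
    acceptor AG (positions -2, -1).  Scanning proceeds upstream from -3; the
    zone stops just downstream of the first AG start found, at the intron
    start, or at ``search_limit`` positions upstream of the 3' ss.  A
    degenerate (empty) zone is returned as an interval of negative length,
    e.g. ``(-2, -3)``.
    """
    n = len(intron_tail)
    if n < 2 or intron_tail[-2:] != "AG":
        raise BranchPointError("intron tail must end with the 3' ss AG")
    lower = -n
    if search_limit is not None:
        lower = max(lower, -search_limit)
    # positions are negative offsets: tail[n + off] is the base at offset off
    d = -2  # empty zone (-2, -3) if an AG starts right at -4/-3
    for off in range(-3, lower - 1, -1):
        if intron_tail[n + off] == "A" and intron_tail[n + off + 1] == "G":
            # AG start at `off`: the zone ends just downstream of its G
            return (off + 2, -3)
        d = off
    return (d, -3)


def pyrimidine_fraction(intron_tail: str, bp_offset: int) -> float:
    """Pyrimidine (C/T) fraction of the interval ``(bp_offset, -3]``.

    Excludes the BP adenine itself and the terminal AG.  An empty interval
    yields 0.0.
    """
    n = len(intron_tail)
    seg = intron_tail[n + bp_offset + 1 : n - 2]
    if not seg:
        return 0.0
    return sum(1 for b in seg if b in "CT") / len(seg)


def best_branch_point(
    intron_tail: str,
    bp_model: PWM,
    dmin: int = 15,
    dmax: int = 100,
    agez_search_limit: Optional[int] = None,
) -> Optional[BPResult]:
    """Highest-scoring BP adenine inside the AGEZ, or ``None``.

    Candidates are every adenine at offset within both the AGEZ and
    ``[-dmax, -dmin]`` that has a full 7-mer context inside the tail.  Ties
    are broken toward the candidate closest to the 3' ss.  Absence of any
    candidate is a value, not an error.
    """
    if bp_model.width != 7:
        raise BranchPointError("BP model must be a 7-position PWM")
    if not dmin < dmax:
        raise BranchPointError("dmin must be smaller than dmax")
    agez = compute_agez(intron_tail, search_limit=agez_search_limit)
    lo = max(agez[0], -dmax)
    hi = min(agez[1], -dmin)
    n = len(intron_tail)
    best: Optional[BPResult] = None
    for off in range(lo, hi + 1):
        if intron_tail[n + off] != "A":
            continue
        start = n + off - BP_POS_IN_HEPTAMER
        stop = start + 7
        if start < 0 or stop > n:
            continue
        s = bp_model.log_odds(intron_tail[start:stop])
        # >= so that on ties the downstream-most (closest to the 3' ss)
        # candidate wins; offsets are scanned upstream-to-downstream
        if best is None or s >= best.score:
            best = BPResult(
                bp_offset=off,
                score=s,
                distance=-off,
                ppt_fraction=pyrimidine_fraction(intron_tail, off),
                agez=agez,
            )
    return best
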