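"""Position weight matrices, IUPAC consensus calling and per-position
conservation comparison for aligned splice-site window sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

#: IUPAC code for each non-empty subset of {A, C, G, T}
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


class MotifError(ValueError):
    pass


@dataclass
class PWM:
    """Per-position base counts/frequencies with information content.

    ``boundary_index`` marks the exon-intron boundary for rendering the
    consensus with a ``|`` bar (the bar is drawn *before* that position).
    """

    counts: np.ndarray  # (width, 4)
    freqs: np.ndarray  # (width, 4), rows sum to 1
    boundary_index: Optional[int] = None
    pseudocount: float = 0.0
    _log_odds_bg: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25), repr=False
    )

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def information_content(self) -> np.ndarray:
        """Per-column IC in bits against a uniform background: 2 - H(column)."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0).sum(axis=1)
        return 2.0 - h

    def log_odds(self, seq: str) -> float:
        """Log2-odds score of a sequence of matching width (bits)."""
        if len(seq) != self.width:
            raise MotifError(
                f"sequence length {len(seq)} != PWM width {self.width}"
            )
        idx = np.fromiter((_B2I[b] for b in seq), dtype=np.intp, count=len(seq))
        f = self.freqs[np.arange(self.width), idx]
        if np.any(f == 0):
            return float("-inf")
        return float(np.log2(f).sum() - np.log2(self._log_odds_bg[idx]).sum())

    def to_tsv(self) -> str:
        lines = ["pos\t" + "\t".join(BASES)]
        for i in range(self.width):
            lines.append(
                str(i) + "\t" + "\t".join(f"{x:.6g}" for x in self.freqs[i])
            )
        return "\n".join(lines) + "\n"


def build_pwm(
    windows: Sequence[str],
    pseudocount: float = 0.0,
    boundary_index: Optional[int] = None,
) -> PWM:
    """Build a PWM from pre-aligned equal-width windows.

    Splice-site windows are aligned by construction (fixed offsets around
    the exon-intron boundary), so frequencies are read off directly; no
    motif-discovery step is needed.
    """
    if not windows:
        raise MotifError("at least one window required")
    width = len(windows[0])
    counts = np.zeros((width, 4))
    for k, w in enumerate(windows):
        if len(w) != width:
            raise MotifError(
                f"window {k} ({w!r}) has width {len(w)}, expected {width}"
            )
        for i, b in enumerate(w):
            if b not in _B2I:
                raise MotifError(f"window {k}: non-ACGT symbol {b!r}")
            counts[i, _B2I[b]] += 1.0
    smoothed = counts + pseudocount
    freqs = smoothed / smoothed.sum(axis=1, keepdims=True)
    return PWM(
        counts=counts, freqs=freqs, boundary_index=boundary_index,
        pseudocount=pseudocount,
    )


def iupac_consensus(
    pwm: PWM,
    single_threshold: float = 0.5,
    single_ratio: float = 2.0,
    pair_threshold: float = 0.75,
) -> str:
    """Cavener-style IUPAC consensus with the exon-intron boundary bar.

    Per column: the single most frequent base if its frequency exceeds
    ``single_threshold`` and is more than ``single_ratio`` times the runner
    up; else the two-base ambiguity code if the top pair sums to more than
    ``pair_threshold``; else ``N``.
    """
    out: List[str] = []
    for i in range(pwm.width):
        col = pwm.freqs[i]
        order = np.argsort(col, kind="stable")[::-1]
        f1, f2 = col[order[0]], col[order[1]]
        if f1 > single_threshold and f1 > single_ratio * f2:
            out.append(BASES[order[0]])
        elif f1 + f2 > pair_threshold:
            out.append(IUPAC[frozenset(BASES[order[0]] + BASES[order[1]])])
        else:
            out.append("N")
    if pwm.boundary_index is not None:
        out.insert(pwm.boundary_index, "|")
    return "".join(out)


def compare_positionwise_conservation(
    set_a: np.ndarray,
    set_b: np.ndarray,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    adjust: Optional[str] = None,
) -> Tuple[np.ndarray, int]:
    """Per-position Mann-Whitney comparison of two conservation-score sets.

    ``set_a`` and ``set_b`` are arrays of shape ``(n_windows, width)`` with
    one per-base conservation score per window position.  Returns the
    p-value vector (length ``width``) and the number of positions with
    ``p < alpha``.  ``alternative`` may be ``"two-sided"``, ``"less"`` or
    ``"greater"`` (directional: is A less/greater than B); ``adjust="bh"``
    applies a Benjamini-Hochberg correction across positions (off by
    default — raw per-position significance is reported otherwise).
    """
    from .stats import mann_whitney_u  # deferred: stats imports nothing from here

    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise MotifError("both sets must be 2-D with equal widths")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise MotifError("each set needs at least two windows")
    pvals = np.array(
        [
            mann_whitney_u(a[:, i], b[:, i], alternative=alternative)[1]
            for i in range(a.shape[1])
        ]
    )
    if adjust == "bh":
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, j in enumerate(order[::-1]):
            k = m - rank_from_top
            running = min(running, pvals[j] * m / k)
            adj[j] = running
        pvals = adj
    return pvals, int(np.sum(pvals < alpha))
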