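"""Splicing-regulatory-element (SRE) scanning and density profiling.

Three kinds of motif resource are supported:

``list``
    A set of fixed-width motifs (RESCUE-ESE / FAS-ESS hexamers, PESE/PESS
    octamers style); a match is any position whose k-mer is in the set,
    overlaps counted.
``pssm``
    A 4 x k scoring matrix with a calling threshold; a match is any window
    scoring at or above the threshold.
``scored_table``
    Experimentally assessed target sequences each carrying a signed score
    (SpliceAid style).  In flanking introns, a positive-score match counts
    as an intronic splicing silencer (ISS) and a negative-score match as an
    intronic splicing enhancer (ISE) — the sign convention of the source
    database, applied exactly as published.  Zero scores are rejected at
    load time because they cannot be classified.

Densities are counts per scanned base; for exons the denominator is the
exon length, for flanking introns the length actually scanned.  Flanking
windows are 300 bp by default and are truncated at the neighbouring
canonical exon when the intron is shorter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .catalog import ExonRecord

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 300


class ResourceError(ValueError):
    pass


@dataclass
class MotifResource:
    """A named SRE motif set with its class label and match rule."""

    name: str
    cls: str  # ESE | ESS | intron_scored
    kind: str  # list | pssm | scored_table
    k: int = 0
    motifs: frozenset = frozenset()
    matrix: Optional[np.ndarray] = None  # (4, k) for pssm
    threshold: Optional[float] = None
    scored_entries: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.cls not in ("ESE", "ESS", "intron_scored"):
            raise ResourceError(f"{self.name}: invalid class {self.cls!r}")
        if self.kind == "list":
            if not self.motifs:
                raise ResourceError(f"{self.name}: empty motif list")
            widths = {len(m) for m in self.motifs}
            if len(widths) != 1:
                raise ResourceError(f"{self.name}: inconsistent motif widths {widths}")
            self.k = widths.pop()
        elif self.kind == "pssm":
            if self.matrix is None or self.threshold is None:
                raise ResourceError(f"{self.name}: pssm needs a matrix and threshold")
            if not np.isfinite(self.threshold):
                raise ResourceError(f"{self.name}: non-finite threshold")
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape[0] != 4:
                raise ResourceError(f"{self.name}: pssm matrix must have 4 rows")
            self.k = self.matrix.shape[1]
        elif self.kind == "scored_table":
            if not self.scored_entries:
                raise ResourceError(f"{self.name}: empty scored table")
            for seq, score in self.scored_entries:
                if not np.isfinite(score) or score == 0:
                    raise ResourceError(
                        f"{self.name}: entry {seq!r} has unusable score {score!r} "
                        f"(zero scores cannot be sign-classified)"
                    )
            self.k = max(len(s) for s, _ in self.scored_entries)
        else:
            raise ResourceError(f"{self.name}: unknown kind {self.kind!r}")


@dataclass
class SREProfile:
    """Per-exon SRE counts/densities; intronic parts filled separately."""

    counts: Dict[str, int] = field(default_factory=dict)
    densities: Dict[str, float] = field(default_factory=dict)
    total_ese_count: int = 0
    total_ess_count: int = 0
    total_ese_density: float = 0.0
    total_ess_density: float = 0.0
    ese_ess_ratio: Optional[float] = None
    iss_density_5p: Optional[float] = None
    ise_density_5p: Optional[float] = None
    iss_density_3p: Optional[float] = None
    ise_density_3p: Optional[float] = None
    iss_ise_ratio: Optional[float] = None
    scanned_exon_length: int = 0
    scanned_up_length: int = 0
    scanned_down_length: int = 0


# ---------------------------------------------------------------------------
# loading


def load_motif_resource(path, name: str, kind: str, cls: str) -> MotifResource:
    """Load a motif resource file of the declared kind.

    Formats: ``list`` — one motif per line; ``pssm`` — a ``#threshold``
    header line then four tab-separated rows (A, C, G, T) of k columns;
    ``scored_table`` — tab-separated ``sequence  score  [factor]`` lines.
    ``#`` comment lines are ignored everywhere (except the pssm threshold
    header).  Duplicate list motifs are collapsed with a warning.
    """
    with open(path) as fh:
        raw = fh.read()
    if "\r" in raw:
        raise ResourceError(f"{path}: CRLF corruption detected")
    lines = [ln for ln in raw.split("\n") if ln.strip()]

    if kind == "list":
        motifs: List[str] = []
        for ln in lines:
            if ln.startswith("#"):
                continue
            m = ln.strip().upper()
            if set(m) - set("ACGT"):
                raise ResourceError(f"{path}: non-ACGT symbol in motif {m!r}")
            motifs.append(m)
        if len(set(motifs)) != len(motifs):
            warnings.warn(f"{path}: duplicate motifs collapsed", stacklevel=2)
        return MotifResource(name=name, cls=cls, kind="list", motifs=frozenset(motifs))

    if kind == "pssm":
        threshold = None
        rows = []
        for ln in lines:
            if ln.startswith("#threshold"):
                threshold = float(ln.split("\t")[1])
            elif ln.startswith("#"):
                continue
            else:
                rows.append([float(x) for x in ln.split("\t")])
        if threshold is None:
            raise ResourceError(f"{path}: pssm file lacks a '#threshold' line")
        if len(rows) != 4:
            raise ResourceError(f"{path}: pssm needs exactly 4 base rows, got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ResourceError(f"{path}: pssm rows differ in width")
        return MotifResource(
            name=name, cls=cls, kind="pssm",
            matrix=np.array(rows), threshold=threshold,
        )

    if kind == "scored_table":
        entries: List[Tuple[str, float]] = []
        n_pos = n_neg = 0
        for ln in lines:
            if ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                raise ResourceError(f"{path}: scored table line needs sequence<TAB>score")
            seq = parts[0].strip().upper()
            if set(seq) - set("ACGT"):
                raise ResourceError(f"{path}: non-ACGT symbol in {seq!r}")
            score = float(parts[1])
            entries.append((seq, score))
            if score > 0:
                n_pos += 1
            else:
                n_neg += 1
        logger.info(
            "%s: loaded %d scored entries (%d positive, %d negative)",
            name, len(entries), n_pos, n_neg,
        )
        return MotifResource(
            name=name, cls=cls, kind="scored_table", scored_entries=tuple(entries)
        )

    raise ResourceError(f"unknown resource kind {kind!r}")


# ---------------------------------------------------------------------------
# counting


def _pssm_window_score(matrix: np.ndarray, window: str) -> float:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return float(sum(matrix[idx[b], i] for i, b in enumerate(window)))


def count_matches(r: MotifResource, seq: str, overlapping: bool = True) -> int:
    """Number of motif matches in ``seq`` (overlapping starts by default)."""
    if set(seq) - set("ACGT"):
        raise ResourceError("sequence has non-ACGT symbols")
    if r.kind == "scored_table":
        pos, neg = count_scored_matches(r, seq, overlapping)
        return pos + neg
    n, k = len(seq), r.k
    if n < k:
        return 0
    count = 0
    i = 0
    while i <= n - k:
        window = seq[i : i + k]
        hit = (
            window in r.motifs
            if r.kind == "list"
            else _pssm_window_score(r.matrix, window) >= r.threshold
        )
        if hit:
            count += 1
            i += 1 if overlapping else k
        else:
            i += 1
    return count


def count_scored_matches(
    r: MotifResource, seq: str, overlapping: bool = True
) -> Tuple[int, int]:
    """(positive-score, negative-score) match counts for a scored table.

    A position matching several entries of the same sign counts once per
    entry; this mirrors per-motif counting of the other kinds, where each
    resource entry is an independent motif.
    """
    if r.kind != "scored_table":
        raise ResourceError("count_scored_matches requires a scored_table resource")
    n_pos = n_neg = 0
    for entry, score in r.scored_entries:
        k = len(entry)
        i = 0
        while i <= len(seq) - k:
            if seq[i : i + k] == entry:
                if score > 0:
                    n_pos += 1
                else:
                    n_neg += 1
                i += 1 if overlapping else k
            else:
                i += 1
    return n_pos, n_neg


# ---------------------------------------------------------------------------
# profiles


def exonic_sre_profile(
    seq: str, resources: Sequence[MotifResource], overlapping: bool = True
) -> SREProfile:
    """Per-resource and total ESE/ESS counts and densities for one exon."""
    for r in resources:
        if r.cls not in ("ESE", "ESS"):
            raise ResourceError(
                f"{r.name}: exonic profiling requires ESE/ESS resources"
            )
    prof = SREProfile(scanned_exon_length=len(seq))
    L = len(seq)
    for r in resources:
        c = count_matches(r, seq, overlapping)
        prof.counts[r.name] = c
        prof.densities[r.name] = c / L if L else 0.0
        if r.cls == "ESE":
            prof.total_ese_count += c
        else:
            prof.total_ess_count += c
    if L:
        prof.total_ese_density = prof.total_ese_count / L
        prof.total_ess_density = prof.total_ess_count / L
    if prof.total_ess_count > 0:
        prof.ese_ess_ratio = prof.total_ese_count / prof.total_ess_count
    else:
        logger.info("no ESS matches: ESE:ESS ratio left absent")
    return prof


def flanking_windows(
    exon: ExonRecord, w: int = DEFAULT_FLANK
) -> Tuple[Optional[Tuple[int, int]], Optional[Tuple[int, int]]]:
    """Genomic intervals of the flanking intronic windows, transcript sense.

    Returns ``(upstream, downstream)`` where *upstream* is the acceptor
    (3' ss) side and *downstream* the donor (5' ss) side in transcript
    orientation.  Each window has length ``min(w, intron length up to the
    neighbouring canonical exon)``; a side is ``None`` when the neighbour
    boundary is unknown (transcript terminus), and a zero-length intron
    yields an empty interval.
    """
    if exon.strand == "+":
        up_gap = None if exon.prev_ce_end is None else exon.start - exon.prev_ce_end
        down_gap = None if exon.next_ce_start is None else exon.next_ce_start - exon.end
    else:
        up_gap = None if exon.next_ce_start is None else exon.next_ce_start - exon.end
        down_gap = None if exon.prev_ce_end is None else exon.start - exon.prev_ce_end
    for gap in (up_gap, down_gap):
        if gap is not None and gap < 0:
            raise ResourceError(
                f"{exon.id}: negative intron length {gap} — inconsistent annotation"
            )
    up = down = None
    if exon.strand == "+":
        if up_gap is not None:
            upw = min(w, up_gap)
            up = (exon.start - upw, exon.start)
        if down_gap is not None:
            dww = min(w, down_gap)
            down = (exon.end, exon.end + dww)
    else:
        if up_gap is not None:
            upw = min(w, up_gap)
            up = (exon.end, exon.end + upw)
        if down_gap is not None:
            dww = min(w, down_gap)
            down = (exon.start - dww, exon.start)
    return up, down


def intronic_sre_profile(
    up_seq: Optional[str],
    down_seq: Optional[str],
    r: MotifResource,
    overlapping: bool = True,
    profile: Optional[SREProfile] = None,
) -> SREProfile:
    """Per-side ISS/ISE densities from a signed scored-table resource.

    ``up_seq`` is the acceptor-side (3' ss) window, ``down_seq`` the
    donor-side (5' ss) window, both transcript sense.  ISS = positive-score
    matches, ISE = negative-score matches.  The ISS:ISE ratio pools both
    sides and is absent when no ISE matches exist.
    """
    if r.cls != "intron_scored":
        raise ResourceError(f"{r.name}: intronic profiling requires an intron-scored resource")
    prof = profile or SREProfile()
    tot_iss = tot_ise = 0
    for side, seq in (("3p", up_seq), ("5p", down_seq)):
        if seq is None or len(seq) == 0:
            continue
        iss, ise = count_scored_matches(r, seq, overlapping)
        tot_iss += iss
        tot_ise += ise
        L = len(seq)
        if side == "3p":
            prof.iss_density_3p, prof.ise_density_3p = iss / L, ise / L
            prof.scanned_up_length = L
        else:
            prof.iss_density_5p, prof.ise_density_5p = iss / L, ise / L
            prof.scanned_down_length = L
    if tot_ise > 0:
        prof.iss_ise_ratio = tot_iss / tot_ise
    return prof
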