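"""Parsing, formatting and application of HGVS-like variant descriptions.

Supported forms (g., c. and r. levels, optionally prefixed by a reference
accession such as ``NC_000023.10:`` or ``NM_004006.2:``):

* substitutions        ``c.7310-19A>G``, ``g.31792328T>C``
* deletions            ``c.100_117del``, ``g.100delA``
* insertions           ``c.100_101insACT`` and interval insertions at RNA
  level such as ``r.7309_7310ins7310-18_7310-1`` (the inserted tract given
  as a coordinate span rather than literal bases)
* deletion-insertions  ``c.100_102delinsTT``

Inversions and complex rearrangements are rejected with an explicit error.
Genomic coordinates inside :class:`VariantRecord` are 1-based plus-strand
(the HGVS surface); interval arithmetic elsewhere in the package is 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import reverse_complement

from .transcript import CPos, CoordinateError, TranscriptMap


class HGVSError(ValueError):
    """Raised for malformed or unsupported HGVS descriptions."""


_CPOS = r"\d+(?:[+-]\d+)?"


def _parse_cpos(tok: str) -> CPos:
    m = re.fullmatch(r"(\d+)([+-]\d+)?", tok)
    if not m:
        raise HGVSError(f"cannot parse position {tok!r}")
    return CPos(int(m.group(1)), int(m.group(2) or 0))


@dataclass
class VariantRecord:
    """A parsed small variant.

    ``ref``/``alt`` and ``g_pos`` are plus-strand genomic (1-based) when the
    variant is genomic or has been mapped through a transcript map; for pure
    c./r. records without a map they hold transcript-sense alleles.
    """

    kind: str  # snv | del | ins | delins | rearrangement
    level: str  # g | c | r
    ref: str = ""
    alt: str = ""
    g_pos: Optional[int] = None  # 1-based start (for ins: base 5' of insertion)
    g_end: Optional[int] = None  # 1-based end, inclusive
    hgvs_g: Optional[str] = None
    hgvs_c: Optional[str] = None
    c_anchor: Optional[CPos] = None
    c_end: Optional[CPos] = None
    ins_length: Optional[int] = None
    accession: Optional[str] = None
    raw: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.kind == "snv":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise HGVSError(
                    f"invalid SNV alleles ref={self.ref!r} alt={self.alt!r}"
                )


def interval_length(a: CPos, b: CPos, tmap: Optional[TranscriptMap] = None) -> int:
    """Number of bases spanned by the closed coordinate interval [a, b].

    With a transcript map the two anchors are mapped to genomic positions and
    the genomic span is returned.  Without a map the span can still be
    computed when both ends anchor the same coding base (a purely intronic
    tract, e.g. ``7310-18`` .. ``7310-1`` -> 18) or when both are plain
    exonic positions.
    """
    if tmap is not None:
        ga, gb = tmap.c_to_g(a), tmap.c_to_g(b)
        return abs(gb - ga) + 1
    if a.pos == b.pos and a.offset != 0 and b.offset != 0:
        return abs(b.offset - a.offset) + 1
    if a.offset == 0 and b.offset == 0:
        return b.pos - a.pos + 1
    raise HGVSError(
        "interval spans an exon boundary; a transcript map is required to "
        "compute its length"
    )


# ---------------------------------------------------------------------------

_RE_SNV = re.compile(rf"({_CPOS})([ACGT])>([ACGT])$")
_RE_DEL = re.compile(rf"({_CPOS})(?:_({_CPOS}))?del([ACGT]*)$")
_RE_INS_SEQ = re.compile(rf"({_CPOS})_({_CPOS})ins([ACGT]+)$")
_RE_INS_IVL = re.compile(rf"({_CPOS})_({_CPOS})ins({_CPOS})_({_CPOS})$")
_RE_DELINS = re.compile(rf"({_CPOS})(?:_({_CPOS}))?delins([ACGT]+)$")
_UNSUPPORTED = ("inv", "dup", "con", "t(", "fs")


def parse_hgvs(desc: str, tmap: Optional[TranscriptMap] = None) -> VariantRecord:
    """Parse an HGVS-like description into a :class:`VariantRecord`.

    When ``tmap`` is given, c.-level records are additionally mapped to
    genomic coordinates (alleles reverse-complemented on the minus strand)
    and a ``hgvs_g`` surface is synthesised, and vice versa.
    """
    desc = desc.strip()
    if not desc or any(c in desc for c in "\r\n\t"):
        raise HGVSError(f"malformed description {desc!r}")
    accession = None
    body = desc
    if ":" in body:
        accession, body = body.split(":", 1)
    m = re.match(r"([gcr])\.(.*)$", body)
    if not m:
        raise HGVSError(f"missing or unsupported coordinate level in {desc!r}")
    level, rest = m.group(1), m.group(2)
    for tag in _UNSUPPORTED:
        if tag in rest:
            raise HGVSError(f"unsupported HGVS form in {desc!r} ({tag!r})")

    rec: VariantRecord
    if mm := _RE_SNV.fullmatch(rest):
        pos, ref, alt = mm.groups()
        rec = VariantRecord(kind="snv", level=level, ref=ref, alt=alt, raw=desc)
        _attach_pos(rec, pos, None, level)
    elif mm := _RE_INS_IVL.fullmatch(rest):
        a, b, ia, ib = mm.groups()
        rec = VariantRecord(kind="ins", level=level, raw=desc)
        _attach_pos(rec, a, b, level)
        rec.ins_length = interval_length(_parse_cpos(ia), _parse_cpos(ib), tmap)
        rec.alt = ""  # bases unknown without a sequence source
        rec._ins_interval = (ia, ib)  # type: ignore[attr-defined]
    elif mm := _RE_INS_SEQ.fullmatch(rest):
        a, b, seq = mm.groups()
        rec = VariantRecord(kind="ins", level=level, alt=seq, raw=desc)
        _attach_pos(rec, a, b, level)
        rec.ins_length = len(seq)
    elif mm := _RE_DELINS.fullmatch(rest):
        a, b, seq = mm.groups()
        rec = VariantRecord(kind="delins", level=level, alt=seq, raw=desc)
        _attach_pos(rec, a, b or a, level)
    elif mm := _RE_DEL.fullmatch(rest):
        a, b, seq = mm.groups()
        rec = VariantRecord(kind="del", level=level, ref=seq or "", raw=desc)
        _attach_pos(rec, a, b or a, level)
    else:
        raise HGVSError(f"unsupported HGVS form: {desc!r}")

    rec.accession = accession
    if level == "g":
        rec.hgvs_g = desc
    else:
        rec.hgvs_c = desc
        if tmap is not None:
            _map_to_genomic(rec, tmap)
    return rec


def _attach_pos(rec: VariantRecord, a: str, b: Optional[str], level: str) -> None:
    if level == "g":
        pa = _parse_cpos(a)
        if pa.offset:
            raise HGVSError("offsets are not valid at the g. level")
        rec.g_pos = pa.pos
        if b is not None:
            pb = _parse_cpos(b)
            if pb.offset:
                raise HGVSError("offsets are not valid at the g. level")
            rec.g_end = pb.pos
        else:
            rec.g_end = rec.g_pos
    else:
        rec.c_anchor = _parse_cpos(a)
        rec.c_end = _parse_cpos(b) if b is not None else rec.c_anchor


def _map_to_genomic(rec: VariantRecord, tmap: TranscriptMap) -> None:
    assert rec.c_anchor is not None
    try:
        g0 = tmap.c_to_g(rec.c_anchor)
        g1 = tmap.c_to_g(rec.c_end) if rec.c_end else g0
    except CoordinateError as exc:
        raise HGVSError(str(exc)) from exc
    lo, hi = min(g0, g1), max(g0, g1)
    rec.g_pos, rec.g_end = lo + 1, hi + 1  # to 1-based
    if tmap.strand == "-":
        ref = reverse_complement(rec.ref) if rec.ref else rec.ref
        alt = reverse_complement(rec.alt) if rec.alt else rec.alt
    else:
        ref, alt = rec.ref, rec.alt
    if rec.kind == "snv":
        rec.hgvs_g = f"g.{rec.g_pos}{ref}>{alt}"
    rec._g_ref, rec._g_alt = ref, alt  # type: ignore[attr-defined]


def format_hgvs(rec: VariantRecord) -> str:
    """Reconstruct the HGVS string for a parsed record (round-trip identity)."""
    prefix = f"{rec.accession}:" if rec.accession else ""
    if rec.level == "g":
        a, b = str(rec.g_pos), str(rec.g_end)
    else:
        a, b = str(rec.c_anchor), str(rec.c_end)
    lvl = rec.level
    if rec.kind == "snv":
        return f"{prefix}{lvl}.{a}{rec.ref}>{rec.alt}"
    if rec.kind == "ins":
        ivl = getattr(rec, "_ins_interval", None)
        insert = f"{ivl[0]}_{ivl[1]}" if ivl else rec.alt
        return f"{prefix}{lvl}.{a}_{b}ins{insert}"
    if rec.kind == "delins":
        span = a if a == b else f"{a}_{b}"
        return f"{prefix}{lvl}.{span}delins{rec.alt}"
    if rec.kind == "del":
        span = a if a == b else f"{a}_{b}"
        return f"{prefix}{lvl}.{span}del{rec.ref}"
    raise HGVSError(f"cannot format record of kind {rec.kind!r}")


# ---------------------------------------------------------------------------


class ReferenceMismatch(ValueError):
    """The variant's reference allele disagrees with the supplied sequence."""


def apply_variant(
    seq: str,
    v: VariantRecord,
    seq_origin: int,
    orientation: str = "+",
) -> str:
    """Apply a variant with known genomic coordinates to a sequence slice.

    Parameters
    ----------
    seq
        The sequence of the genomic interval ``[seq_origin, seq_origin+len)``
        — plus-strand when ``orientation`` is ``"+"``, reverse-complemented
        (transcript-sense of a minus-strand gene) when ``"-"``.
    seq_origin
        0-based plus-strand genomic coordinate of the slice start.
    """
    if v.g_pos is None:
        raise HGVSError("variant has no genomic coordinates; map it first")
    if orientation not in "+-":
        raise ValueError(f"invalid orientation {orientation!r}")
    plus = seq if orientation == "+" else reverse_complement(seq)
    start0 = v.g_pos - 1 - seq_origin
    end0 = v.g_end - seq_origin  # half-open
    if start0 < 0 or end0 > len(plus):
        raise HGVSError("variant lies outside the supplied sequence slice")
    ref = getattr(v, "_g_ref", v.ref) if v.level != "g" else v.ref
    alt = getattr(v, "_g_alt", v.alt) if v.level != "g" else v.alt
    if v.kind == "snv":
        observed = plus[start0]
        if observed != ref:
            raise ReferenceMismatch(
                f"expected {ref!r} at g.{v.g_pos}, observed {observed!r}"
            )
        out = plus[:start0] + alt + plus[start0 + 1 :]
    elif v.kind == "del":
        if ref and plus[start0:end0] != ref:
            raise ReferenceMismatch(
                f"expected {ref!r} at g.{v.g_pos}_{v.g_end}, "
                f"observed {plus[start0:end0]!r}"
            )
        out = plus[:start0] + plus[end0:]
    elif v.kind == "ins":
        if not alt:
            raise HGVSError("insertion without literal bases cannot be applied")
        # g_pos is the base 5' of the insertion point
        out = plus[: start0 + 1] + alt + plus[start0 + 1 :]
    elif v.kind == "delins":
        out = plus[:start0] + alt + plus[end0:]
    else:
        raise HGVSError(f"cannot apply variant of kind {v.kind!r}")
    return out if orientation == "+" else reverse_complement(out)
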