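"""Data model and I/O for the curated pseudoexon catalog.

A *pseudoexon* (PE) is an intronic tract that is spliced into the mature
mRNA as if it were an exon; only PEs activated by a pathogenic genomic
variant are admitted to the catalog.  This module holds the exon/PE record
types, the catalog TSV reader with its inclusion-criteria checks, the
mechanism-based group assignment, poison-exon flagging (highly conserved +
premature termination codon), and catalog summary statistics.

Catalog TSV schema (tab-separated, header required; ``#`` lines ignored)::

    pe_id  chrom  start  end  strand  mechanism  variants  variant_class
    phenotype  ptc_offset  conservation_mean

* ``start``/``end``  — 0-based half-open plus-strand genomic coordinates
* ``mechanism``      — comma-separated subset of
  {new_ss, strengthen_cryptic_ss, new_ESE, disrupt_ESS}
* ``variants``       — semicolon-separated HGVS-like descriptions; an empty
  field violates the inclusion criterion that every PE must have an
  activating genomic variant and the row is rejected
* ``variant_class``  — snv | small_deletion | large_rearrangement
* ``ptc_offset``     — 0-based offset of a premature termination codon from
  the PE 5' end, empty if none
* ``conservation_mean`` — mean per-base constraint score (GERP-like scale)

Unknown columns are ignored with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Seq import reverse_complement

from .hgvs import HGVSError, VariantRecord, parse_hgvs
from .transcript import TranscriptMap

logger = logging.getLogger(__name__)

MECHANISMS = frozenset({"new_ss", "strengthen_cryptic_ss", "new_ESE", "disrupt_ESS"})
SS_MECHANISMS = frozenset({"new_ss", "strengthen_cryptic_ss"})

#: default "highly conserved" cutoff on a GERP-like scale (configurable; the
#: flag is always reported together with the threshold that produced it)
DEFAULT_CONSERVATION_THRESHOLD = 2.0

STOP_CODONS = {"TAA", "TAG", "TGA"}


class CatalogError(ValueError):
    """Schema or inclusion-criterion violation in a catalog file."""


@dataclass
class ExonRecord:
    """A canonical exon (CE) or pseudoexon (PE) interval with its sequence.

    ``seq`` is stored in transcript-sense orientation (reverse-complemented
    at extraction for minus-strand genes); ``start``/``end`` stay 0-based
    half-open plus-strand genomic.
    """

    id: str
    role: str  # "CE" | "PE"
    chrom: str
    start: int
    end: int
    strand: str = "+"
    seq: str = ""
    prev_ce_end: Optional[int] = None
    next_ce_start: Optional[int] = None
    conservation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CatalogError(f"{self.id}: end must exceed start")
        if self.role not in ("CE", "PE"):
            raise CatalogError(f"{self.id}: role must be CE or PE")
        if self.strand not in "+-":
            raise CatalogError(f"{self.id}: invalid strand {self.strand!r}")
        if self.seq:
            if len(self.seq) != self.end - self.start:
                raise CatalogError(
                    f"{self.id}: sequence length {len(self.seq)} != interval "
                    f"length {self.end - self.start}"
                )
            if set(self.seq) - set("ACGT"):
                raise CatalogError(f"{self.id}: sequence has non-ACGT symbols")
        if self.conservation is not None:
            self.conservation = np.asarray(self.conservation, dtype=float)
            if self.seq and len(self.conservation) != len(self.seq):
                raise CatalogError(
                    f"{self.id}: conservation vector length mismatch"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PERecord:
    """A catalogued pseudoexon: its interval, activating variant(s), mechanism."""

    exon: ExonRecord
    variants: List[VariantRecord]
    mechanism: Set[str]
    variant_class: str = "snv"
    phenotype: str = ""
    ptc_offset: Optional[int] = None
    conservation_mean: Optional[float] = None
    poison_flag: bool = False
    group: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.mechanism) - MECHANISMS
        if unknown:
            raise CatalogError(
                f"{self.exon.id}: unknown mechanism(s) {sorted(unknown)}"
            )
        if self.poison_flag and self.ptc_offset is None:
            raise CatalogError(f"{self.exon.id}: poison flag without a PTC offset")


@dataclass
class CatalogSummary:
    n_total: int
    n_snv_activated: int
    n_rearrangement_or_small: int
    pct_snv: Optional[float]
    pct_other: Optional[float]
    n_group_splice_site: int
    n_group_sre: int
    n_poison: int


# ---------------------------------------------------------------------------


def assign_group(pe: PERecord) -> str:
    """Mechanism-based group: ``splice_site`` or ``SRE``.

    Any splice-site mechanism (new site creation or cryptic-site
    strengthening) takes precedence: records carrying both a splice-site and
    an SRE mechanism go to the splice-site group.  The poison flag never
    changes the group; it is an orthogonal label.
    """
    if not pe.mechanism:
        raise CatalogError(f"{pe.exon.id}: empty mechanism set")
    return "splice_site" if pe.mechanism & SS_MECHANISMS else "SRE"


def flag_poison_exon(
    pe: ExonRecord,
    frame_phase: int,
    downstream_cds: str,
    cons_threshold: Optional[float] = DEFAULT_CONSERVATION_THRESHOLD,
) -> Tuple[bool, Optional[int]]:
    """Poison-exon test: highly conserved AND introduces an in-frame PTC.

    ``frame_phase`` is the number of bases of the codon in progress at the PE
    5' end (0 means the PE starts on a codon boundary).  Translation walks
    the PE sequence continued into ``downstream_cds`` and reports the 0-based
    offset (from the PE 5' end) of the first stop codon, which may lie
    downstream of the PE itself when the PE length shifts the reading frame.
    """
    if frame_phase not in (0, 1, 2):
        raise ValueError("frame_phase must be 0, 1 or 2")
    combined = pe.seq + downstream_cds.upper()
    first_codon_start = (3 - frame_phase) % 3
    ptc_offset: Optional[int] = None
    for i in range(first_codon_start, len(combined) - 2, 3):
        if combined[i : i + 3] in STOP_CODONS:
            ptc_offset = i
            break
    if cons_threshold is None:
        conserved = True
    else:
        if pe.conservation is None:
            raise CatalogError(
                f"{pe.id}: conservation vector required for the poison-exon "
                f"test with a finite threshold"
            )
        conserved = bool(float(np.mean(pe.conservation)) >= cons_threshold)
    return (conserved and ptc_offset is not None), ptc_offset


def summarize_catalog(records: Sequence[PERecord]) -> CatalogSummary:
    """Counts and percentages by activating-variant class and by group."""
    n = len(records)
    n_snv = sum(1 for r in records if r.variant_class == "snv")
    n_other = n - n_snv
    if n:
        pct_snv: Optional[float] = round(100.0 * n_snv / n, 2)
        pct_other: Optional[float] = round(100.0 * n_other / n, 2)
    else:
        pct_snv = pct_other = None
    groups = [r.group or assign_group(r) for r in records]
    return CatalogSummary(
        n_total=n,
        n_snv_activated=n_snv,
        n_rearrangement_or_small=n_other,
        pct_snv=pct_snv,
        pct_other=pct_other,
        n_group_splice_site=sum(1 for g in groups if g == "splice_site"),
        n_group_sre=sum(1 for g in groups if g == "SRE"),
        n_poison=sum(1 for r in records if r.poison_flag),
    )


# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "pe_id",
    "chrom",
    "start",
    "end",
    "strand",
    "mechanism",
    "variants",
    "variant_class",
    "phenotype",
    "ptc_offset",
    "conservation_mean",
]
_VARIANT_CLASSES = {"snv", "small_deletion", "large_rearrangement"}


@dataclass
class RejectedRow:
    pe_id: str
    line_no: int
    reason: str


def _read_tsv_lines(path) -> List[Tuple[int, str]]:
    with open(path, "r", newline="") as fh:
        raw = fh.read()
    if "\r" in raw:
        raise CatalogError(f"{path}: CRLF or stray carriage returns detected")
    out = []
    for i, line in enumerate(raw.split("\n"), start=1):
        if not line or line.startswith("#"):
            continue
        if line != line.strip(" "):
            raise CatalogError(f"{path}:{i}: leading/trailing whitespace corruption")
        out.append((i, line))
    return out


def load_catalog(
    path,
    fasta: Optional[Dict[str, str]] = None,
    ce_intervals: Optional[Sequence[Tuple[str, int, int]]] = None,
    tmap: Optional[TranscriptMap] = None,
    cons_threshold: Optional[float] = DEFAULT_CONSERVATION_THRESHOLD,
) -> Tuple[List[PERecord], List[RejectedRow]]:
    """Load the curated PE catalog, enforcing the inclusion criteria.

    Rows are rejected (with a logged reason) rather than erroring when they
    violate an inclusion criterion: a PE overlapping a canonical exon, or a
    PE without an activating genomic variant.  Structural problems in the
    file itself (bad header, malformed fields) raise :class:`CatalogError`
    naming the row and column.

    ``fasta`` may be any mapping from chromosome name to plus-strand
    sequence (a ``pyfaidx.Fasta`` works); sequences are extracted in
    transcript-sense orientation.  Returns ``(records, rejected)``.
    """
    lines = _read_tsv_lines(path)
    if not lines:
        raise CatalogError(f"{path}: empty catalog")
    header = lines[0][1].split("\t")
    for col in _CATALOG_COLUMNS:
        if col not in header:
            raise CatalogError(f"{path}: missing required column {col!r}")
    extra = [c for c in header if c not in _CATALOG_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    idx = {c: header.index(c) for c in _CATALOG_COLUMNS}

    records: List[PERecord] = []
    rejected: List[RejectedRow] = []
    for line_no, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < len(header):
            raise CatalogError(f"{path}:{line_no}: expected {len(header)} columns")

        def get(col: str) -> str:
            return fields[idx[col]].strip()

        pe_id = get("pe_id")
        try:
            start, end = int(get("start")), int(get("end"))
        except ValueError as exc:
            raise CatalogError(f"{path}:{line_no}: column start/end: {exc}") from exc

        variant_field = get("variants")
        if not variant_field:
            # inclusion criterion: a PE without a pathogenic activating
            # variant at the genomic level is not included
            rejected.append(RejectedRow(pe_id, line_no, "criterion 4: no activating variant"))
            logger.info("rejected %s (line %d): no activating variant", pe_id, line_no)
            continue
        if ce_intervals is not None:
            chrom = get("chrom")
            overlap = any(
                c == chrom and start < ce_e and ce_s < end
                for (c, ce_s, ce_e) in ce_intervals
            )
            if overlap:
                rejected.append(
                    RejectedRow(pe_id, line_no, "criterion 2: overlaps a canonical exon")
                )
                logger.info("rejected %s (line %d): overlaps CE", pe_id, line_no)
                continue

        strand = get("strand")
        seq = ""
        if fasta is not None:
            chrom_seq = fasta[get("chrom")]
            plus = str(chrom_seq[start:end]).upper()
            if end > len(chrom_seq) or not plus or len(plus) != end - start:
                raise CatalogError(f"{path}:{line_no}: interval outside sequence bounds")
            seq = plus if strand == "+" else reverse_complement(plus)

        mech_field = get("mechanism")
        mechanism = {m for m in mech_field.split(",") if m} if mech_field else set()
        bad = mechanism - MECHANISMS
        if bad:
            raise CatalogError(
                f"{path}:{line_no}: column mechanism: unknown value(s) {sorted(bad)}"
            )
        vclass = get("variant_class")
        if vclass not in _VARIANT_CLASSES:
            raise CatalogError(
                f"{path}:{line_no}: column variant_class: {vclass!r} not in "
                f"{sorted(_VARIANT_CLASSES)}"
            )
        try:
            variants = [parse_hgvs(v, tmap=tmap) for v in variant_field.split(";")]
        except HGVSError:
            # large rearrangements are catalogued descriptively only
            if vclass == "large_rearrangement":
                variants = [
                    VariantRecord(kind="rearrangement", level="g", raw=variant_field)
                ]
            else:
                raise CatalogError(
                    f"{path}:{line_no}: column variants: cannot parse "
                    f"{variant_field!r}"
                )

        ptc_raw = get("ptc_offset")
        ptc_offset = int(ptc_raw) if ptc_raw else None
        cons_raw = get("conservation_mean")
        cons_mean = float(cons_raw) if cons_raw else None
        if cons_threshold is None:
            poison = ptc_offset is not None
        else:
            poison = (
                ptc_offset is not None
                and cons_mean is not None
                and cons_mean >= cons_threshold
            )

        exon = ExonRecord(
            id=pe_id, role="PE", chrom=get("chrom"), start=start, end=end,
            strand=strand, seq=seq,
        )
        rec = PERecord(
            exon=exon,
            variants=variants,
            mechanism=mechanism,
            variant_class=vclass,
            phenotype=get("phenotype"),
            ptc_offset=ptc_offset,
            conservation_mean=cons_mean,
            poison_flag=poison,
        )
        rec.group = assign_group(rec)
        records.append(rec)
    return records, rejected


def read_bed6(path) -> List[ExonRecord]:
    """Read canonical-exon intervals from a BED6 file."""
    exons = []
    for line_no, line in _read_tsv_lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise CatalogError(f"{path}:{line_no}: BED6 requires 6 columns")
        exons.append(
            ExonRecord(
                id=f[3], role="CE", chrom=f[0], start=int(f[1]), end=int(f[2]),
                strand=f[5],
            )
        )
    return exons
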