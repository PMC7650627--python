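"""Configuration-driven orchestration: catalog -> per-exon features ->
consensus motifs -> group comparisons -> TSV/JSON report bundle.

The feature table carries, per exon: length; donor and acceptor strengths
under each enabled model family (models trained on the canonical-exon
splice-site windows of the same locus); branch-point distance and
pyrimidine content inside the AG exclusion zone; per-resource exonic SRE
densities, totals and the ESE:ESS ratio; and per-side intronic ISS/ISE
densities over (truncated) 300 bp flanking windows.  Pseudoexon sites and
bodies are scored on the *mutant* sequence (activating variants applied).

Groups for comparison: canonical exons (CE), splice-site-mechanism PEs,
SRE-mechanism PEs, and possible poison exons.  By default the poison group
overlaps the mechanism groups (a poison PE contributes a second, poison-
labelled row); a disjointness switch removes the mechanism-group copy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .branch_point import best_branch_point
from .catalog import (
    ExonRecord,
    PERecord,
    load_catalog,
    read_bed6,
    summarize_catalog,
)
from .consensus_motif import PWM, build_pwm, iupac_consensus
from .hgvs import apply_variant
from .sre_scan import (
    MotifResource,
    count_matches,
    exonic_sre_profile,
    flanking_windows,
    intronic_sre_profile,
    load_motif_resource,
)
from .splice_models import (
    ACCEPTOR_WIDTH,
    DONOR_WIDTH,
    SiteModel,
    SiteWindow,
    SpliceModelError,
    delta_splice_scores,
    train_site_model,
)
from .stats import GroupComparisonResult, compare_groups
from .transcript import TranscriptMap

logger = logging.getLogger(__name__)

DEFAULT_MODEL_KINDS = ("wmm", "mm1", "maxent", "mdd", "sspct")

#: acceptor consensus-motif window: 22 intronic + 1 exonic positions (the
#: rendering dialect used for 3' ss logos); independent of the 23-position
#: scoring window convention (20 intronic + 3 exonic)
ACCEPTOR_MOTIF_INTRONIC = 22


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    fasta: Path
    bed: Path
    catalog: Path
    tmap: Optional[Path] = None
    resource_specs: Sequence[Tuple[str, str, str, str]] = ()  # (path, name, kind, cls)
    conservation: Optional[Path] = None
    out_dir: Path = Path("pexsplice_out")
    model_kinds: Sequence[str] = DEFAULT_MODEL_KINDS
    flank_window: int = 300
    alpha: float = 0.05
    poison_groups_disjoint: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    features: pd.DataFrame
    comparisons: List[GroupComparisonResult]
    summary: dict
    motifs: Dict[str, PWM]
    consensus: Dict[str, str]
    paths: Dict[str, Path]


# ---------------------------------------------------------------------------
# window extraction


def _read_fasta(path: Path) -> Dict[str, str]:
    seqs: Dict[str, List[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.strip().upper())
    return {k: "".join(v) for k, v in seqs.items()}


def exon_site_windows(
    chrom_seq: str, exon: ExonRecord
) -> Tuple[Optional[str], Optional[str]]:
    """(acceptor 23-mer, donor 9-mer) around an exon, transcript sense.

    A side is ``None`` at a transcript terminus (a first canonical exon has
    no acceptor, a last one no donor) or when the window would run off the
    sequence.  Pseudoexons always have both flanking introns.
    """
    from Bio.Seq import reverse_complement

    no_acc = exon.role == "CE" and (
        exon.prev_ce_end is None if exon.strand == "+" else exon.next_ce_start is None
    )
    no_don = exon.role == "CE" and (
        exon.next_ce_start is None if exon.strand == "+" else exon.prev_ce_end is None
    )
    if exon.strand == "+":
        acc = chrom_seq[exon.start - 20 : exon.start + 3]
        don = chrom_seq[exon.end - 3 : exon.end + 6]
    else:
        acc = reverse_complement(chrom_seq[exon.end - 3 : exon.end + 20])
        don = reverse_complement(chrom_seq[exon.start - 6 : exon.start + 3])
    acc = None if (no_acc or len(acc) != ACCEPTOR_WIDTH) else acc
    don = None if (no_don or len(don) != DONOR_WIDTH) else don
    return acc, don


def acceptor_motif_window(chrom_seq: str, exon: ExonRecord) -> Optional[str]:
    """The 3' ss consensus-motif window: 22 intronic + 1 exonic positions."""
    from Bio.Seq import reverse_complement

    if exon.role == "CE" and (
        exon.prev_ce_end is None if exon.strand == "+" else exon.next_ce_start is None
    ):
        return None
    if exon.strand == "+":
        w = chrom_seq[exon.start - ACCEPTOR_MOTIF_INTRONIC : exon.start + 1]
    else:
        w = reverse_complement(
            chrom_seq[exon.end - 1 : exon.end + ACCEPTOR_MOTIF_INTRONIC]
        )
    return w if len(w) == ACCEPTOR_MOTIF_INTRONIC + 1 else None


def mutant_region(
    chrom_seq: str, pe: PERecord, pad: int = 60
) -> Tuple[str, int]:
    """Chromosome slice around a PE with its activating SNVs applied.

    Returns (plus-strand mutant slice, slice origin).  Variants without
    genomic coordinates (descriptive rearrangements) are skipped with a log
    notice; length-changing variants are applied but shift downstream
    coordinates within the slice.
    """
    lo = max(0, pe.exon.start - pad)
    hi = min(len(chrom_seq), pe.exon.end + pad)
    region = chrom_seq[lo:hi]
    for v in pe.variants:
        if v.g_pos is None:
            logger.info("%s: variant %r not applicable to sequence", pe.exon.id, v.raw)
            continue
        if not (lo < v.g_pos <= hi):
            logger.info("%s: variant %r outside the PE region", pe.exon.id, v.raw)
            continue
        region = apply_variant(region, v, seq_origin=lo, orientation="+")
    return region, lo


# ---------------------------------------------------------------------------
# model training on canonical sites


def train_models(
    ce_acceptors: Sequence[str],
    ce_donors: Sequence[str],
    kinds: Sequence[str] = DEFAULT_MODEL_KINDS,
    pseudocount: float = 0.5,
) -> Dict[str, Dict[str, SiteModel]]:
    """Train every requested model family on canonical splice-site windows."""
    out: Dict[str, Dict[str, SiteModel]] = {"acceptor": {}, "donor": {}}
    acc_wins = [SiteWindow("acceptor", s, relaxed=True) for s in ce_acceptors]
    don_wins = [SiteWindow("donor", s, relaxed=True) for s in ce_donors]
    for kind in kinds:
        out["acceptor"][kind] = train_site_model(
            kind, "acceptor", acc_wins, pseudocount=pseudocount
        )
        out["donor"][kind] = train_site_model(
            kind, "donor", don_wins, pseudocount=pseudocount
        )
    return out


# ---------------------------------------------------------------------------
# feature extraction


def _exon_features(
    chrom_seq: str,
    exon: ExonRecord,
    exon_seq_override: Optional[str],
    site_windows: Tuple[Optional[str], Optional[str]],
    models: Dict[str, Dict[str, SiteModel]],
    resources: Sequence[MotifResource],
    bp_model: Optional[PWM],
    flank_w: int,
) -> dict:
    from Bio.Seq import reverse_complement

    row: dict = {"exon_id": exon.id, "exon_length": exon.length}
    acc, don = site_windows
    for st, win in (("acceptor", acc), ("donor", don)):
        for kind, model in models.get(st, {}).items():
            key = f"{'3ss' if st == 'acceptor' else '5ss'}_{kind}"
            if win is None:
                row[key] = np.nan
                continue
            try:
                row[key] = model.score(SiteWindow(st, win, relaxed=True))
            except SpliceModelError:
                row[key] = np.nan

    # branch point inside the AGEZ, from the intron tail ending at the 3' ss
    if bp_model is not None and acc is not None:
        if exon.strand == "+":
            tail = chrom_seq[max(0, exon.start - 120) : exon.start]
        else:
            tail = reverse_complement(chrom_seq[exon.end : exon.end + 120])
        bp = (
            best_branch_point(tail, bp_model)
            if tail[-2:] == "AG"
            else None
        )
        row["bp_distance"] = bp.distance if bp else np.nan
        row["bp_score"] = bp.score if bp else np.nan
        row["ppt_fraction"] = bp.ppt_fraction if bp else np.nan

    # exonic SREs on the (mutant, for PEs) exon body
    body = exon_seq_override if exon_seq_override is not None else exon.seq
    exonic = [r for r in resources if r.cls in ("ESE", "ESS")]
    if body and exonic:
        prof = exonic_sre_profile(body, exonic)
        for name, dens in prof.densities.items():
            row[f"density_{name}"] = dens
        row["total_ese_density"] = prof.total_ese_density
        row["total_ess_density"] = prof.total_ess_density
        row["ese_ess_ratio"] = (
            prof.ese_ess_ratio if prof.ese_ess_ratio is not None else np.nan
        )

    scored = [r for r in resources if r.cls == "intron_scored"]
    if scored:
        up, down = flanking_windows(exon, flank_w)

        def seq_of(iv):
            if iv is None:
                return None
            s = chrom_seq[iv[0] : iv[1]]
            return s if exon.strand == "+" else reverse_complement(s)

        prof = intronic_sre_profile(seq_of(up), seq_of(down), scored[0])
        row["iss_density_3ss"] = _nan(prof.iss_density_3p)
        row["ise_density_3ss"] = _nan(prof.ise_density_3p)
        row["iss_density_5ss"] = _nan(prof.iss_density_5p)
        row["ise_density_5ss"] = _nan(prof.ise_density_5p)
        row["iss_ise_ratio"] = _nan(prof.iss_ise_ratio)
    return row


def _nan(x: Optional[float]) -> float:
    return np.nan if x is None else x


def build_feature_table(
    chrom_seqs: Dict[str, str],
    ce_exons: Sequence[ExonRecord],
    pe_records: Sequence[PERecord],
    models: Dict[str, Dict[str, SiteModel]],
    resources: Sequence[MotifResource],
    bp_model: Optional[PWM] = None,
    flank_w: int = 300,
    poison_groups_disjoint: bool = False,
) -> pd.DataFrame:
    """Per-exon feature rows with group labels; PE sites use mutant sequence."""
    rows: List[dict] = []
    for exon in ce_exons:
        seq = chrom_seqs[exon.chrom]
        if not exon.seq:
            exon.seq = (
                seq[exon.start : exon.end]
                if exon.strand == "+"
                else _rc(seq[exon.start : exon.end])
            )
        row = _exon_features(
            seq, exon, None, exon_site_windows(seq, exon), models, resources,
            bp_model, flank_w,
        )
        row["group"] = "CE"
        rows.append(row)
    for pe in pe_records:
        seq = chrom_seqs[pe.exon.chrom]
        region, origin = mutant_region(seq, pe)
        # mutant chromosome view: splice/branch windows read from a patched
        # copy (an indel shifts coordinates only inside the patched slice)
        hi = min(len(seq), pe.exon.end + 60)
        patched = seq[:origin] + region + seq[hi:]
        off = pe.exon.start - origin
        body = region[off : off + pe.exon.length]
        row = _exon_features(
            patched, pe.exon, body, exon_site_windows(patched, pe.exon),
            models, resources, bp_model, flank_w,
        )
        base_group = pe.group or "SRE"
        if pe.poison_flag and poison_groups_disjoint:
            row["group"] = "poison"
            rows.append(row)
        else:
            row["group"] = base_group
            rows.append(row)
            if pe.poison_flag:
                dup = dict(row)
                dup["group"] = "poison"
                rows.append(dup)
    return pd.DataFrame(rows)


def _rc(s: str) -> str:
    from Bio.Seq import reverse_complement

    return reverse_complement(s)


# ---------------------------------------------------------------------------
# mechanism inference (used for planted-truth recovery)


def infer_mechanism(
    chrom_seq: str,
    pe: PERecord,
    models_acceptor: Sequence[SiteModel],
    models_donor: Sequence[SiteModel],
    ese: MotifResource,
    ess: MotifResource,
) -> str:
    """Infer the activation mechanism of a PE from its variant's effect.

    Delta-scores the variant against acceptor and donor models; a
    site-creation or site-strengthening call wins.  Otherwise the exonic
    ESE/ESS match-count changes decide between enhancer creation and
    silencer disruption.  Returns one of the four mechanism labels or
    ``"unknown"``.
    """
    snvs = [v for v in pe.variants if v.g_pos is not None and v.kind == "snv"]
    if not snvs:
        return "unknown"
    v = snvs[0]
    lo = max(0, v.g_pos - 1 - 40)
    hi = min(len(chrom_seq), v.g_pos + 40)
    region = chrom_seq[lo:hi]
    neutral_acc = SiteWindow("acceptor", "C" * 18 + "AG" + "GAA")
    neutral_don = SiteWindow("donor", "CAGGTAAGT")
    best_call = "no_ss_effect"
    for natural, models in (
        (neutral_acc, models_acceptor),
        (neutral_don, models_donor),
    ):
        rep = delta_splice_scores(
            region, v, natural, models, seq_origin=lo, orientation="+"
        )
        if rep.classification == "creates_new_ss":
            best_call = "creates_new_ss"
            break
        if rep.classification == "strengthens_cryptic_ss":
            best_call = "strengthens_cryptic_ss"
    if best_call == "creates_new_ss":
        return "new_ss"
    if best_call == "strengthens_cryptic_ss":
        return "strengthen_cryptic_ss"
    ref_body = chrom_seq[pe.exon.start : pe.exon.end]
    alt_body = apply_variant(
        chrom_seq[pe.exon.start : pe.exon.end], v, seq_origin=pe.exon.start
    ) if pe.exon.start < v.g_pos <= pe.exon.end else ref_body
    d_ese = count_matches(ese, alt_body) - count_matches(ese, ref_body)
    d_ess = count_matches(ess, alt_body) - count_matches(ess, ref_body)
    if d_ese > 0 and d_ese >= -d_ess:
        return "new_ESE"
    if d_ess < 0:
        return "disrupt_ESS"
    return "unknown"


# ---------------------------------------------------------------------------
# the driver


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle.

    Writes ``features.tsv``, ``comparisons.tsv``, ``summary.json``,
    ``motifs/*.tsv`` and ``run.log`` under ``cfg.out_dir``.  Missing optional
    inputs (conservation, motif resources) disable the dependent features
    with a logged notice rather than failing.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("pexsplice")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info(
        "pexsplice %s run started %s seed=%d",
        __version__, datetime.now(timezone.utc).isoformat(), cfg.seed,
    )
    try:
        return _run_stages(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(cfg: PipelineConfig, out: Path) -> PipelineResult:
    # --- load
    try:
        chrom_seqs = _read_fasta(cfg.fasta)
        ce_exons = read_bed6(cfg.bed)
        _link_neighbours(ce_exons)
        tmap = (
            TranscriptMap.from_json(Path(cfg.tmap).read_text())
            if cfg.tmap
            else None
        )
        pes, rejected = load_catalog(
            cfg.catalog,
            fasta=chrom_seqs,
            ce_intervals=[(e.chrom, e.start, e.end) for e in ce_exons],
            tmap=tmap,
        )
        for rej in rejected:
            logger.info("catalog row rejected: %s (%s)", rej.pe_id, rej.reason)
        resources = [
            load_motif_resource(p, name, kind, cls)
            for (p, name, kind, cls) in cfg.resource_specs
        ]
        if not resources:
            logger.info("no motif resources configured; SRE features disabled")
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    # --- neighbour boundaries for PEs
    for pe in pes:
        ex = pe.exon
        ex.prev_ce_end = max(
            (e.end for e in ce_exons if e.chrom == ex.chrom and e.end <= ex.start),
            default=None,
        )
        ex.next_ce_start = min(
            (e.start for e in ce_exons if e.chrom == ex.chrom and e.start >= ex.end),
            default=None,
        )

    # --- models on canonical windows
    try:
        ce_wins = [
            exon_site_windows(chrom_seqs[e.chrom], e) for e in ce_exons
        ]
        accs = [a for a, _ in ce_wins if a]
        dons = [d for _, d in ce_wins if d]
        models = train_models(accs, dons, cfg.model_kinds)
    except Exception as exc:
        raise PipelineError("train_models", str(exc)) from exc

    # --- features
    try:
        from .synthetic_data import BP_SAMPLING_PWM

        bp_model = PWM(counts=BP_SAMPLING_PWM, freqs=BP_SAMPLING_PWM)
        features = build_feature_table(
            chrom_seqs, ce_exons, pes, models, resources,
            bp_model=bp_model, flank_w=cfg.flank_window,
            poison_groups_disjoint=cfg.poison_groups_disjoint,
        )
    except Exception as exc:
        raise PipelineError("features", str(exc)) from exc

    # --- consensus motifs
    motifs: Dict[str, PWM] = {}
    consensus: Dict[str, str] = {}
    try:
        pe_wins = [
            exon_site_windows(chrom_seqs[p.exon.chrom], p.exon) for p in pes
        ]
        exon_sets = (
            ("CE", ce_wins, ce_exons),
            ("PE", pe_wins, [p.exon for p in pes]),
        )
        for label, wins, exons in exon_sets:
            donors = [d for _, d in wins if d]
            accs = [
                w
                for w in (
                    acceptor_motif_window(chrom_seqs[e.chrom], e) for e in exons
                )
                if w
            ]
            if donors:
                motifs[f"{label}_donor"] = build_pwm(donors, boundary_index=3)
            if accs:
                motifs[f"{label}_acceptor"] = build_pwm(
                    accs, boundary_index=ACCEPTOR_MOTIF_INTRONIC
                )
        consensus = {k: iupac_consensus(p) for k, p in motifs.items()}
    except Exception as exc:
        raise PipelineError("motifs", str(exc)) from exc

    # --- comparisons and summary
    try:
        pe_labels = (
            ["splice_site", "SRE", "poison"]
            if cfg.poison_groups_disjoint
            else ["splice_site", "SRE"]
        )
        comparisons = compare_groups(
            features.drop(columns=["exon_id"]), alpha=cfg.alpha,
            pe_labels=pe_labels,
        )
        summary = summarize_catalog(pes)
        summary_d = {
            "n_total": summary.n_total,
            "n_snv_activated": summary.n_snv_activated,
            "n_rearrangement_or_small": summary.n_rearrangement_or_small,
            "pct_snv": summary.pct_snv,
            "pct_other": summary.pct_other,
            "n_group_splice_site": summary.n_group_splice_site,
            "n_group_sre": summary.n_group_sre,
            "n_poison": summary.n_poison,
            "n_rejected_rows": len(rejected),
            "consensus": consensus,
            "seed": cfg.seed,
            "version": __version__,
        }
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    # --- write bundle
    try:
        paths = _write_bundle(out, features, comparisons, summary_d, motifs)
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc
    return PipelineResult(
        features=features, comparisons=comparisons, summary=summary_d,
        motifs=motifs, consensus=consensus, paths=paths,
    )


def _link_neighbours(ce_exons: List[ExonRecord]) -> None:
    by_chrom: Dict[str, List[ExonRecord]] = {}
    for e in ce_exons:
        by_chrom.setdefault(e.chrom, []).append(e)
    for group in by_chrom.values():
        group.sort(key=lambda e: e.start)
        for i, e in enumerate(group):
            e.prev_ce_end = group[i - 1].end if i > 0 else None
            e.next_ce_start = group[i + 1].start if i < len(group) - 1 else None


def _write_bundle(
    out: Path,
    features: pd.DataFrame,
    comparisons: List[GroupComparisonResult],
    summary: dict,
    motifs: Dict[str, PWM],
) -> Dict[str, Path]:
    paths: Dict[str, Path] = {}
    paths["features"] = out / "features.tsv"
    features.to_csv(paths["features"], sep="\t", index=False)
    rows = []
    for r in comparisons:
        row = {
            "feature": r.feature, "kw_h": r.kw_h, "kw_df": r.kw_df,
            "kw_p": r.kw_p, "mwu_u": r.mwu_u, "mwu_p": r.mwu_p,
            "n_missing": r.n_missing,
        }
        for g, summ in r.group_summary.items():
            row[f"n_{g}"] = r.group_n[g]
            for name, val in zip(("min", "q1", "median", "q3", "max"), summ):
                row[f"{g}_{name}"] = val
        if r.nemenyi_p is not None:
            for gi in r.nemenyi_p.index:
                for gj in r.nemenyi_p.columns:
                    if gi < gj:
                        row[f"nemenyi_{gi}_vs_{gj}"] = r.nemenyi_p.loc[gi, gj]
        rows.append(row)
    paths["comparisons"] = out / "comparisons.tsv"
    pd.DataFrame(rows).to_csv(paths["comparisons"], sep="\t", index=False)
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    motif_dir = out / "motifs"
    motif_dir.mkdir(exist_ok=True)
    for name, pwm in motifs.items():
        p = motif_dir / f"{name}.tsv"
        p.write_text(pwm.to_tsv())
        paths[f"motif_{name}"] = p
    paths["log"] = out / "run.log"
    return paths
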