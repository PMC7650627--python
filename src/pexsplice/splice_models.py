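"""Trainable splice-site strength models and variant delta-scoring.

Five model families score fixed-width splice-site windows:

``wmm``
    Weight matrix model: independent per-position frequencies; score is the
    log2 odds against a background base distribution (bits).
``mm1``
    First-order Markov model: initial distribution at the first position and
    position-specific transition tables; log2-odds score.
``maxent``
    Maximum-entropy joint distribution over the whole window, fitted by
    iterative proportional fitting (IPF) to a constraint set (all
    single-position marginals plus all adjacent-pair marginals by default).
    Donor windows are fitted as one full joint table; wider acceptor windows
    use an overlapping-fragment chain decomposition, each fragment at most
    seven positions, combined by the product/quotient rule over the shared
    overlap positions.
``mdd``
    Maximum dependence decomposition: a decision tree that recursively
    splits the training set on the position whose consensus-indicator shows
    the strongest summed chi-square dependence on the remaining positions;
    each leaf holds a WMM.
``sspct``
    Consensus-value percent score over a per-position frequency matrix:
    ``100 * (t - t_min) / (t_max - t_min)`` where ``t`` sums the matrix
    value of the observed base at each position — the score family used by
    percent-scale splice-site web tools.

Window conventions: donor 9-mer = 3 exonic + 6 intronic bases with GT at
intronic positions 1-2; acceptor 23-mer = 20 intronic + 3 exonic bases with
AG at intronic positions -2,-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

DONOR_WIDTH = 9
DONOR_EXONIC = 3  # GT at window indices 3,4
ACCEPTOR_WIDTH = 23
ACCEPTOR_INTRONIC = 20  # AG at window indices 18,19

UNIFORM_BACKGROUND = np.full(4, 0.25)


class SpliceModelError(ValueError):
    pass


class IPFConvergenceError(RuntimeError):
    """IPF failed to reach the marginal tolerance within max iterations."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"IPF did not converge within {max_iter} iterations "
            f"(final marginal residual {residual:.3e})"
        )
        self.residual = residual


@dataclass(frozen=True)
class SiteWindow:
    """A fixed-width splice-site window in transcript-sense orientation."""

    site_type: str  # donor | acceptor
    seq: str
    relaxed: bool = False  # skip the mandatory-dinucleotide check

    def __post_init__(self) -> None:
        if self.site_type not in ("donor", "acceptor"):
            raise SpliceModelError(f"invalid site_type {self.site_type!r}")
        if set(self.seq) - set(BASES):
            raise SpliceModelError(f"non-ACGT symbol in window {self.seq!r}")
        if not self.relaxed:
            width = DONOR_WIDTH if self.site_type == "donor" else ACCEPTOR_WIDTH
            if len(self.seq) != width:
                raise SpliceModelError(
                    f"{self.site_type} window must be {width} nt, got {len(self.seq)}"
                )
            pos = _dinucleotide_slice(self.site_type)
            want = "GT" if self.site_type == "donor" else "AG"
            got = self.seq[pos[0] : pos[1]]
            if got != want:
                raise SpliceModelError(
                    f"mandatory {want} absent at window positions "
                    f"{pos[0]}-{pos[1] - 1} (found {got!r})"
                )


def _dinucleotide_slice(site_type: str) -> Tuple[int, int]:
    return (3, 5) if site_type == "donor" else (18, 20)


def has_mandatory_dinucleotide(site_type: str, seq: str) -> bool:
    a, b = _dinucleotide_slice(site_type)
    want = "GT" if site_type == "donor" else "AG"
    return seq[a:b] == want


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_B2I[b] for b in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise SpliceModelError(f"non-ACGT symbol {exc.args[0]!r}") from exc


def _freq_matrix(windows: Sequence[str], pseudocount: float) -> np.ndarray:
    width = len(windows[0])
    counts = np.zeros((width, 4))
    for w in windows:
        counts[np.arange(width), _encode(w)] += 1.0
    counts += pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model classes


@dataclass
class SiteModel:
    """Base for all splice-site scoring models."""

    kind: str = field(init=False, default="")
    site_type: str = "donor"
    width: int = DONOR_WIDTH
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.5

    def _check(self, w: SiteWindow) -> None:
        if w.site_type != self.site_type:
            raise SpliceModelError(
                f"model is for {self.site_type} sites, window is {w.site_type}"
            )
        if len(w.seq) != self.width:
            raise SpliceModelError(
                f"width mismatch: model {self.width}, window {len(w.seq)}"
            )

    def _log2_bg(self, seq: str) -> float:
        q = 1.0
        for i in _encode(seq):
            q *= self.background[i]
        return math.log2(q)

    def log2_prob(self, seq: str) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def score(self, w: SiteWindow) -> float:
        """Log2 odds in bits (overridden by the percent-score model)."""
        self._check(w)
        return self.log2_prob(w.seq) - self._log2_bg(w.seq)


@dataclass
class WMMModel(SiteModel):
    freqs: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))

    def __post_init__(self) -> None:
        self.kind = "wmm"

    def log2_prob(self, seq: str) -> float:
        p = 1.0
        for i, b in enumerate(_encode(seq)):
            p *= self.freqs[i, b]
        if p == 0.0:
            return -math.inf
        return math.log2(p)


@dataclass
class MM1Model(SiteModel):
    initial: np.ndarray = field(default_factory=lambda: np.zeros(4))
    transitions: List[np.ndarray] = field(default_factory=list)  # [width-1] of 4x4

    def __post_init__(self) -> None:
        self.kind = "mm1"

    def log2_prob(self, seq: str) -> float:
        idx = _encode(seq)
        p = self.initial[idx[0]]
        for i in range(1, len(idx)):
            p *= self.transitions[i - 1][idx[i - 1], idx[i]]
        if p == 0.0:
            return -math.inf
        return math.log2(p)


@dataclass
class MaxEntModel(SiteModel):
    """Maximum-entropy model: either one full joint table or a fragment chain.

    ``tables`` maps a position span ``(start, stop)`` to a fitted joint
    probability array of shape ``(4,)*(stop-start)``; ``overlaps`` lists the
    single positions shared by consecutive fragments, whose marginal
    probabilities are divided out (product/quotient rule).
    """

    tables: Dict[Tuple[int, int], np.ndarray] = field(default_factory=dict)
    overlaps: List[int] = field(default_factory=list)
    marginals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    constraint_set: str = "pairs"  # "singles" | "pairs"
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        self.kind = "maxent"

    def log2_prob(self, seq: str) -> float:
        idx = _encode(seq)
        logp = 0.0
        for (a, b), table in self.tables.items():
            p = table[tuple(idx[a:b])]
            if p == 0.0:
                return -math.inf
            logp += math.log2(p)
        for pos in self.overlaps:
            m = self.marginals[pos, idx[pos]]
            logp -= math.log2(m)
        return logp


@dataclass
class _MDDNode:
    split_pos: Optional[int] = None
    consensus_base: Optional[int] = None
    match: Optional["_MDDNode"] = None
    other: Optional["_MDDNode"] = None
    wmm: Optional[WMMModel] = None
    n: int = 0


@dataclass
class MDDModel(SiteModel):
    root: Optional[_MDDNode] = None
    consensus: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.intp))

    def __post_init__(self) -> None:
        self.kind = "mdd"

    def _leaf(self, seq_idx: np.ndarray) -> _MDDNode:
        node = self.root
        while node.split_pos is not None:
            matches = seq_idx[node.split_pos] == node.consensus_base
            node = node.match if matches else node.other
        return node

    def log2_prob(self, seq: str) -> float:
        return self._leaf(_encode(seq)).wmm.log2_prob(seq)


@dataclass
class PercentScoreModel(SiteModel):
    """Consensus-value percent score over a frequency (or weight) matrix."""

    matrix: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))

    def __post_init__(self) -> None:
        self.kind = "sspct"

    def score(self, w: SiteWindow) -> float:
        self._check(w)
        idx = _encode(w.seq)
        t = float(self.matrix[np.arange(self.width), idx].sum())
        t_min = float(self.matrix.min(axis=1).sum())
        t_max = float(self.matrix.max(axis=1).sum())
        if t_max == t_min:
            return 100.0
        val = 100.0 * (t - t_min) / (t_max - t_min)
        return min(100.0, max(0.0, val))


@dataclass
class LookupTableModel(SiteModel):
    """Scores from an externally published joint probability table.

    The table maps every k-mer window to its model probability; scoring is
    the usual log2 odds against the model's background.  Used for parity
    runs against reference implementations whose fitted tables are
    published; the table layout is one ``KMER<TAB>probability`` pair per
    line (see :func:`load_joint_table`).
    """

    table: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = "maxent_table"

    def log2_prob(self, seq: str) -> float:
        try:
            p = self.table[seq]
        except KeyError as exc:
            raise SpliceModelError(f"window {seq!r} absent from the table") from exc
        return math.log2(p) if p > 0 else -math.inf


def load_joint_table(path, site_type: str, width: int) -> LookupTableModel:
    """Load a published joint probability table (``KMER<TAB>prob`` lines)."""
    table: Dict[str, float] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kmer, _, val = line.partition("\t")
            if len(kmer) != width or set(kmer) - set(BASES):
                raise SpliceModelError(f"{path}:{line_no}: bad k-mer {kmer!r}")
            table[kmer] = float(val)
    return LookupTableModel(site_type=site_type, width=width, table=table)


# ---------------------------------------------------------------------------
# training


def train_site_model(
    kind: str,
    site_type: str,
    training_windows: Sequence[SiteWindow],
    *,
    pseudocount: float = 0.5,
    background: Optional[np.ndarray] = None,
    maxent_constraints: str = "pairs",
    ipf_tol: float = 1e-6,
    ipf_max_iter: int = 500,
    max_fragment_width: int = 7,
    mdd_p_threshold: float = 1e-3,
    mdd_min_leaf: int = 25,
) -> SiteModel:
    """Train a splice-site model of the requested family.

    All windows must share the model's width and site type.  For ``maxent``
    the constraint set is all single-position marginals (``"singles"``) or
    additionally all adjacent-pair marginals (``"pairs"``, default), fitted
    by IPF; windows wider than nine positions are decomposed into a chain of
    overlapping fragments of at most ``max_fragment_width`` positions.
    """
    if not training_windows:
        raise SpliceModelError("at least one training window required")
    seqs = [w.seq for w in training_windows]
    width = len(seqs[0])
    for w in training_windows:
        if w.site_type != site_type or len(w.seq) != width:
            raise SpliceModelError("training windows differ in width or site type")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    common = dict(site_type=site_type, width=width, background=bg, pseudocount=pseudocount)

    if kind == "wmm":
        return WMMModel(freqs=_freq_matrix(seqs, pseudocount), **common)
    if kind == "sspct":
        return PercentScoreModel(matrix=_freq_matrix(seqs, pseudocount), **common)
    if kind == "mm1":
        return _train_mm1(seqs, **common)
    if kind == "maxent":
        return _train_maxent(
            seqs, constraint_set=maxent_constraints, tol=ipf_tol,
            max_iter=ipf_max_iter, max_fragment_width=max_fragment_width, **common,
        )
    if kind == "mdd":
        return _train_mdd(
            seqs, p_threshold=mdd_p_threshold, min_leaf=mdd_min_leaf, **common
        )
    raise SpliceModelError(f"unknown model kind {kind!r}")


def _train_mm1(seqs: Sequence[str], **common) -> MM1Model:
    width = common["width"]
    pc = common["pseudocount"]
    enc = np.stack([_encode(s) for s in seqs])
    init_counts = np.bincount(enc[:, 0], minlength=4).astype(float) + pc
    transitions = []
    for i in range(1, width):
        t = np.zeros((4, 4))
        for prev, cur in zip(enc[:, i - 1], enc[:, i]):
            t[prev, cur] += 1.0
        t += pc
        rows = t.sum(axis=1, keepdims=True)
        # an unobserved previous base (possible at pseudocount 0) gets a
        # uniform transition row rather than 0/0
        t = np.where(rows > 0, t / np.where(rows > 0, rows, 1.0), 0.25)
        transitions.append(t)
    return MM1Model(initial=init_counts / init_counts.sum(), transitions=transitions, **common)


def _pair_marginals(enc: np.ndarray, width: int, pc: float) -> List[np.ndarray]:
    """Empirical adjacent-pair distributions, pseudocount pc/4 per cell so the
    implied single marginals match the single-position targets exactly."""
    out = []
    for i in range(width - 1):
        t = np.zeros((4, 4))
        for a, b in zip(enc[:, i], enc[:, i + 1]):
            t[a, b] += 1.0
        t += pc / 4.0
        out.append(t / t.sum())
    return out


def _ipf_fit(
    singles: List[np.ndarray],
    pairs: Optional[List[np.ndarray]],
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, float]:
    """Fit the maximum-entropy joint table by iterative proportional fitting.

    Deterministic initialisation from the product of the single-position
    constraints; cycles over single then adjacent-pair constraints until the
    worst (L-infinity) marginal residual is within ``tol``.
    """
    width = len(singles)
    table = np.ones((4,) * width)
    for i, f in enumerate(singles):
        shape = [1] * width
        shape[i] = 4
        table = table * f.reshape(shape)

    def residual() -> float:
        r = 0.0
        for i, f in enumerate(singles):
            axes = tuple(a for a in range(width) if a != i)
            r = max(r, float(np.abs(table.sum(axis=axes) - f).max()))
        if pairs is not None:
            for i, pt in enumerate(pairs):
                axes = tuple(a for a in range(width) if a not in (i, i + 1))
                r = max(r, float(np.abs(table.sum(axis=axes) - pt).max()))
        return r

    res = residual()
    it = 0
    while res > tol:
        if it >= max_iter:
            raise IPFConvergenceError(res, max_iter)
        for i, f in enumerate(singles):
            axes = tuple(a for a in range(width) if a != i)
            m = table.sum(axis=axes)
            factor = np.where(m > 0, f / np.where(m > 0, m, 1.0), 1.0)
            shape = [1] * width
            shape[i] = 4
            table *= factor.reshape(shape)
        if pairs is not None:
            for i, pt in enumerate(pairs):
                axes = tuple(a for a in range(width) if a not in (i, i + 1))
                m = table.sum(axis=axes)
                factor = np.where(m > 0, pt / np.where(m > 0, m, 1.0), 1.0)
                shape = [1] * width
                shape[i] = 4
                shape[i + 1] = 4
                table *= factor.reshape(shape)
        it += 1
        res = residual()
    return table, res


def _train_maxent(
    seqs: Sequence[str],
    constraint_set: str,
    tol: float,
    max_iter: int,
    max_fragment_width: int,
    **common,
) -> MaxEntModel:
    width = common["width"]
    pc = common["pseudocount"]
    enc = np.stack([_encode(s) for s in seqs])
    marginals = _freq_matrix(seqs, pc)

    if width <= 9:
        spans = [(0, width)]
        overlaps: List[int] = []
    else:
        spans = []
        s = 0
        while True:
            e = min(s + max_fragment_width, width)
            spans.append((s, e))
            if e == width:
                break
            s = e - 1  # chain with single-position overlap
        overlaps = [a for (a, _b) in spans[1:]]

    tables: Dict[Tuple[int, int], np.ndarray] = {}
    worst = 0.0
    for (a, b) in spans:
        singles = [marginals[i] for i in range(a, b)]
        pairs = (
            _pair_marginals(enc[:, a:b], b - a, pc)
            if constraint_set == "pairs"
            else None
        )
        table, res = _ipf_fit(singles, pairs, tol, max_iter)
        tables[(a, b)] = table
        worst = max(worst, res)
    return MaxEntModel(
        tables=tables, overlaps=overlaps, marginals=marginals,
        constraint_set=constraint_set, fit_residual=worst, **common,
    )


def _chi2_stat_2x4(ind: np.ndarray, bases: np.ndarray) -> float:
    """Pearson chi-square of a consensus-indicator x base contingency table."""
    obs = np.zeros((2, 4))
    for r, c in zip(ind, bases):
        obs[int(r), int(c)] += 1.0
    n = obs.sum()
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    exp = rows * cols / n
    mask = exp > 0
    return float((((obs - exp) ** 2)[mask] / exp[mask]).sum())


def _train_mdd(seqs: Sequence[str], p_threshold: float, min_leaf: int, **common) -> MDDModel:
    width = common["width"]
    pc = common["pseudocount"]
    enc = np.stack([_encode(s) for s in seqs])
    counts = np.zeros((width, 4))
    for row in enc:
        counts[np.arange(width), row] += 1.0
    consensus = counts.argmax(axis=1)
    crit = chi2.isf(p_threshold, df=3) if p_threshold > 0 else math.inf
    model = MDDModel(consensus=consensus, **common)

    def leaf(idx: np.ndarray) -> _MDDNode:
        sub = [seqs[i] for i in idx]
        wmm = WMMModel(
            freqs=_freq_matrix(sub, pc), site_type=common["site_type"],
            width=width, background=common["background"], pseudocount=pc,
        )
        return _MDDNode(wmm=wmm, n=len(idx))

    def build(idx: np.ndarray) -> _MDDNode:
        n = len(idx)
        if n < 2 * min_leaf:
            return leaf(idx)
        sub = enc[idx]
        best_pos, best_sum, best_max = -1, -1.0, 0.0
        for i in range(width):
            ind = (sub[:, i] == consensus[i]).astype(int)
            if ind.min() == ind.max():
                continue  # no variation at this position in this node
            stats = [
                _chi2_stat_2x4(ind, sub[:, j]) for j in range(width) if j != i
            ]
            s = float(np.sum(stats))
            if s > best_sum:
                best_pos, best_sum, best_max = i, s, float(np.max(stats))
        if best_pos < 0 or best_max < crit:
            return leaf(idx)
        ind = enc[idx][:, best_pos] == consensus[best_pos]
        idx_m, idx_o = idx[ind], idx[~ind]
        if len(idx_m) < min_leaf or len(idx_o) < min_leaf:
            return leaf(idx)
        node = _MDDNode(
            split_pos=best_pos, consensus_base=int(consensus[best_pos]), n=n
        )
        node.match = build(idx_m)
        node.other = build(idx_o)
        return node

    model.root = build(np.arange(len(seqs)))
    return model


def score_site(model: SiteModel, w: SiteWindow) -> float:
    """Score a window with a trained model (bits, or percent for ``sspct``)."""
    return model.score(w)


# ---------------------------------------------------------------------------
# variant delta-scoring


@dataclass
class ModelDelta:
    kind: str
    post_score: float
    post_start: Optional[int]  # window start in the mutant region, transcript sense
    pre_score: float
    pre_valid: bool  # aligned reference window has the dinucleotide and clears the floor
    site_called: bool  # the post-variant window itself clears the calling floor
    natural_score: float

    @property
    def delta(self) -> float:
        return self.post_score - self.pre_score

    @property
    def stronger_than_natural(self) -> bool:
        return self.post_score > self.natural_score


@dataclass
class DeltaScoreReport:
    classification: str  # creates_new_ss | strengthens_cryptic_ss | no_ss_effect
    deltas: Dict[str, ModelDelta]


def _best_window(
    model: SiteModel, region: str, lo: int, hi: int
) -> Tuple[Optional[int], float]:
    """Best valid (dinucleotide-bearing) window whose span overlaps [lo, hi)."""
    W = model.width
    best_start, best_score = None, -math.inf
    for start in range(max(0, lo - W + 1), min(len(region) - W, hi - 1) + 1):
        sub = region[start : start + W]
        if not has_mandatory_dinucleotide(model.site_type, sub):
            continue
        s = model.score(SiteWindow(model.site_type, sub, relaxed=True))
        if s > best_score:
            best_start, best_score = start, s
    return best_start, best_score


def delta_splice_scores(
    ref_region: str,
    v,
    natural_site: SiteWindow,
    models: Sequence[SiteModel],
    *,
    seq_origin: int,
    orientation: str = "+",
    floor_bits: float = 0.0,
    floor_pct: float = 65.0,
) -> DeltaScoreReport:
    """Rescore every window overlapping a variant and classify its effect.

    The mutant region is built by applying ``v``; for every model the best
    post-variant window (mandatory dinucleotide required) overlapping the
    edited span is found, the aligned pre-variant window is scored
    regardless of its dinucleotide, and the report classifies the variant:

    * ``creates_new_ss`` — some model calls a site after the variant (post
      score at or above the calling floor) while no model's aligned
      pre-variant window was callable (dinucleotide absent or score below
      the floor);
    * ``strengthens_cryptic_ss`` — a pre-existing callable site gains score;
    * ``no_ss_effect`` — otherwise (in particular when no post-variant
      window clears the floor: a chance AG/GT near the variant is not a
      site call).
    """
    from .hgvs import apply_variant  # local import to avoid a cycle

    alt_region = apply_variant(ref_region, v, seq_origin, orientation)
    # variant span in transcript-sense region coordinates
    g_lo = v.g_pos - 1 - seq_origin
    g_hi = v.g_end - seq_origin
    if orientation == "+":
        lo, hi = g_lo, g_hi
    else:
        lo, hi = len(ref_region) - g_hi, len(ref_region) - g_lo
    shift = len(alt_region) - len(ref_region)
    alt_hi = hi + shift if v.kind != "snv" else hi

    deltas: Dict[str, ModelDelta] = {}
    any_candidate = False
    for model in models:
        if model.site_type != natural_site.site_type:
            raise SpliceModelError("models and natural site must share a site type")
        natural = model.score(natural_site)
        floor = floor_pct if model.kind == "sspct" else floor_bits
        post_start, post_score = _best_window(model, alt_region, lo, max(alt_hi, lo + 1))
        if post_start is None:
            deltas[model.kind] = ModelDelta(
                kind=model.kind, post_score=0.0, post_start=None,
                pre_score=0.0, pre_valid=False, site_called=False,
                natural_score=natural,
            )
            continue
        any_candidate = True
        # align the reference window to the post-variant hit
        ref_start = post_start if post_start <= lo else post_start - shift
        ref_start = min(max(ref_start, 0), max(len(ref_region) - model.width, 0))
        ref_sub = ref_region[ref_start : ref_start + model.width]
        pre_score = model.score(SiteWindow(model.site_type, ref_sub, relaxed=True))
        pre_valid = (
            has_mandatory_dinucleotide(model.site_type, ref_sub)
            and pre_score >= floor
        )
        deltas[model.kind] = ModelDelta(
            kind=model.kind, post_score=post_score, post_start=post_start,
            pre_score=pre_score, pre_valid=pre_valid,
            site_called=post_score >= floor, natural_score=natural,
        )

    called = [d for d in deltas.values() if d.site_called]
    if not any_candidate or not called:
        classification = "no_ss_effect"
    elif not any(d.pre_valid for d in deltas.values() if d.post_start is not None):
        classification = "creates_new_ss"
    elif any(d.delta > 0 for d in called):
        classification = "strengthens_cryptic_ss"
    else:
        classification = "no_ss_effect"
    return DeltaScoreReport(classification=classification, deltas=deltas)
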