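"""Splice-site strength models: training identities, oracles and deltas."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from pexsplice.hgvs import parse_hgvs
from pexsplice.splice_models import (
    MaxEntModel,
    SiteWindow,
    SpliceModelError,
    delta_splice_scores,
    score_site,
    train_site_model,
)

BASES = "ACGT"


def _random_windows(rng, n, width=9, site_type="donor"):
    return [
        SiteWindow(site_type, "".join(rng.choice(list(BASES), width)), relaxed=True)
        for _ in range(n)
    ]


class TestWMM:
    def test_degenerate_training_set_scores_window_width_times_two_bits(self):
        """n identical 9-mers, zero pseudocount, uniform background: the
        training window is certain under the model, so the log-odds is
        9 * log2(4) = 18 bits."""
        win = SiteWindow("donor", "CAGGTAAGT")
        model = train_site_model("wmm", "donor", [win] * 5, pseudocount=0.0)
        assert score_site(model, win) == pytest.approx(18.0)

    def test_normalization(self):
        rng = np.random.default_rng(0)
        model = train_site_model("wmm", "donor", _random_windows(rng, 20))
        assert np.allclose(model.freqs.sum(axis=1), 1.0, atol=1e-9)


class TestMM1:
    def test_hand_computed_log_odds(self):
        """First-order Markov scores match an independent hand calculation
        on a four-sequence toy training set (pseudocount 0)."""
        seqs = ["AACC", "AACG", "ACGG", "CCGG"]
        wins = [SiteWindow("donor", s, relaxed=True) for s in seqs]
        model = train_site_model("mm1", "donor", wins, pseudocount=0.0)
        # oracle: direct frequency bookkeeping
        query = "AACC"
        p = 3 / 4  # P(pos0 = A)
        p *= 2 / 3  # P(A->A at pos1): of 3 A's at pos0, 2 followed by A
        p *= 2 / 2  # P(A->C at pos2): both pos1 A's followed by C
        p *= 1 / 2  # P(C->C at pos3): pos2 C's (from AACC, AACG) -> C once
        expected = math.log2(p / 0.25**4)
        got = score_site(model, SiteWindow("donor", query, relaxed=True))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_rows_normalize(self):
        rng = np.random.default_rng(1)
        model = train_site_model("mm1", "donor", _random_windows(rng, 30))
        assert np.allclose(model.initial.sum(), 1.0, atol=1e-9)
        for t in model.transitions:
            assert np.allclose(t.sum(axis=1), 1.0, atol=1e-9)


class TestMaxEnt:
    def test_position_only_constraints_reproduce_wmm_bitwise(self):
        """With only single-position marginal constraints the maximum-entropy
        distribution is the product of marginals, i.e. the weight matrix
        model — scores agree bitwise over 1,000 seeded windows."""
        rng = np.random.default_rng(42)
        train = _random_windows(rng, 50)
        wmm = train_site_model("wmm", "donor", train)
        me = train_site_model(
            "maxent", "donor", train, maxent_constraints="singles"
        )
        probe = _random_windows(rng, 1000)
        for w in probe:
            assert score_site(me, w) == score_site(wmm, w)

    def test_pair_constraint_marginals_within_tolerance(self):
        rng = np.random.default_rng(7)
        train = _random_windows(rng, 40)
        me = train_site_model("maxent", "donor", train)
        assert isinstance(me, MaxEntModel)
        table = me.tables[(0, 9)]
        assert me.fit_residual <= 1e-6
        assert abs(table.sum() - 1.0) < 1e-9
        # independently recompute empirical marginals and compare
        enc = np.stack(
            [[BASES.index(b) for b in w.seq] for w in train]
        )
        for i in range(9):
            emp = np.bincount(enc[:, i], minlength=4) + 0.5
            emp = emp / emp.sum()
            axes = tuple(a for a in range(9) if a != i)
            assert np.abs(table.sum(axis=axes) - emp).max() <= 1e-6

    def test_entropy_dominates_empirical_on_small_window(self):
        """On a 4^6 toy the fitted maximum-entropy joint has entropy at least
        that of the empirical distribution (exhaustive check)."""
        rng = np.random.default_rng(3)
        # a skewed source so the empirical distribution is far from uniform
        probs = np.array([0.5, 0.3, 0.1, 0.1])
        seqs = [
            "".join(rng.choice(list(BASES), 6, p=probs)) for _ in range(60)
        ]
        wins = [SiteWindow("donor", s, relaxed=True) for s in seqs]
        me = train_site_model("maxent", "donor", wins, pseudocount=0.0)
        table = me.tables[(0, 6)]
        h_fit = -np.sum(table[table > 0] * np.log2(table[table > 0]))
        counts = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        emp = np.array(list(counts.values()), dtype=float) / len(seqs)
        h_emp = -np.sum(emp * np.log2(emp))
        assert h_fit >= h_emp - 1e-9

    def test_acceptor_fragment_chain_scores_are_finite_and_reasonable(self):
        rng = np.random.default_rng(9)
        train = _random_windows(rng, 40, width=23, site_type="acceptor")
        me = train_site_model("maxent", "acceptor", train)
        assert len(me.tables) > 1  # fragment decomposition used
        for (a, b), t in me.tables.items():
            assert b - a <= 7 and abs(t.sum() - 1.0) < 1e-9
        s = score_site(me, train[0])
        assert np.isfinite(s)


class TestMDD:
    def test_root_split_recovers_planted_dependence(self):
        """Position 2 is G iff position 5 is A (plus noise elsewhere): the
        tree must split on one of the two dependent positions, and the
        chosen position must maximize the summed chi-square computed by an
        exhaustive scipy-based oracle."""
        rng = np.random.default_rng(5)
        seqs = []
        for _ in range(200):
            s = list("".join(rng.choice(list(BASES), 9)))
            if rng.random() < 0.5:
                s[5] = "A"
                s[2] = "G"
            else:
                s[5] = rng.choice(list("CGT"))
                s[2] = rng.choice(list("ACT"))
            seqs.append("".join(s))
        wins = [SiteWindow("donor", s, relaxed=True) for s in seqs]
        model = train_site_model(
            "mdd", "donor", wins, mdd_min_leaf=20, mdd_p_threshold=1e-3
        )
        assert model.root.split_pos is not None

        # oracle: summed chi-square per position, exhaustively
        enc = np.stack([[BASES.index(b) for b in s] for s in seqs])
        consensus = [
            np.bincount(enc[:, i], minlength=4).argmax() for i in range(9)
        ]

        def s_i(i):
            ind = (enc[:, i] == consensus[i]).astype(int)
            tot = 0.0
            for j in range(9):
                if j == i:
                    continue
                tab = np.zeros((2, 4))
                for r, c in zip(ind, enc[:, j]):
                    tab[r, c] += 1
                tab = tab[:, tab.sum(axis=0) > 0]
                tot += chi2_contingency(tab, correction=False)[0]
            return tot

        sums = [s_i(i) for i in range(9)]
        assert model.root.split_pos == int(np.argmax(sums))
        assert model.root.split_pos in (2, 5)

    def test_infinite_threshold_degenerates_to_wmm(self):
        rng = np.random.default_rng(8)
        wins = _random_windows(rng, 120)
        mdd = train_site_model("mdd", "donor", wins, mdd_p_threshold=0.0)
        wmm = train_site_model("wmm", "donor", wins)
        for w in _random_windows(rng, 50):
            assert score_site(mdd, w) == score_site(wmm, w)


class TestPercentScore:
    def test_bounds_at_argmax_and_argmin(self):
        rng = np.random.default_rng(2)
        wins = _random_windows(rng, 30)
        model = train_site_model("sspct", "donor", wins)
        best = "".join(BASES[i] for i in model.matrix.argmax(axis=1))
        worst = "".join(BASES[i] for i in model.matrix.argmin(axis=1))
        assert score_site(model, SiteWindow("donor", best, relaxed=True)) == 100.0
        assert score_site(model, SiteWindow("donor", worst, relaxed=True)) == 0.0

    def test_monotone_in_matrix_value(self):
        rng = np.random.default_rng(4)
        model = train_site_model("sspct", "donor", _random_windows(rng, 30))
        base = "".join(BASES[i] for i in model.matrix.argmin(axis=1))
        prev = 0.0
        seq = list(base)
        for pos in range(9):
            seq[pos] = BASES[int(model.matrix[pos].argmax())]
            cur = score_site(model, SiteWindow("donor", "".join(seq), relaxed=True))
            assert cur >= prev
            prev = cur


class TestWindowValidation:
    def test_width_mismatch_errors(self):
        model = train_site_model(
            "wmm", "donor", [SiteWindow("donor", "CAGGTAAGT")]
        )
        with pytest.raises(SpliceModelError, match="width"):
            score_site(model, SiteWindow("donor", "CAGGTA", relaxed=True))

    def test_mandatory_dinucleotide_violation_names_positions(self):
        with pytest.raises(SpliceModelError, match="positions 3-4"):
            SiteWindow("donor", "CAGCTAAGT")
        with pytest.raises(SpliceModelError, match="positions 18-19"):
            SiteWindow("acceptor", "C" * 23)

    def test_site_type_mismatch(self):
        model = train_site_model(
            "wmm", "donor", [SiteWindow("donor", "CAGGTAAGT")]
        )
        with pytest.raises(SpliceModelError, match="site"):
            score_site(model, SiteWindow("acceptor", "C" * 18 + "AG" + "CTG"))


@pytest.fixture(scope="module")
def acceptor_models():
    from pexsplice.synthetic_data import sample_training_windows

    wins = sample_training_windows(123, "acceptor", 200)
    return [
        train_site_model("wmm", "acceptor", wins),
        train_site_model("sspct", "acceptor", wins),
    ]


class TestDeltaScores:
    NATURAL = SiteWindow("acceptor", "C" * 18 + "AG" + "GAA")

    def test_variant_far_from_any_window_is_no_effect(self, acceptor_models):
        rng = np.random.default_rng(11)
        region = "".join(rng.choice(list("CT"), 120))  # pyrimidines: no AG at all
        v = parse_hgvs("g.1060C>T")
        region = region[:59] + "C" + region[60:]
        rep = delta_splice_scores(
            region, v, self.NATURAL, acceptor_models, seq_origin=1000
        )
        assert rep.classification == "no_ss_effect"
        assert all(d.post_start is None for d in rep.deltas.values())

    def test_cg_to_ag_in_pyrimidine_tract_creates_site(self, acceptor_models):
        """An SNV converting CG to AG downstream of a long pyrimidine tract
        creates an acceptor; the best post-variant window equals the
        exhaustive rescan maximum."""
        tract = "TCTTTCTTTTTCCTTTCTTT"
        region = "TTTTTT" + tract + "CG" + "GAAATTTTTT"
        v_pos = 1000 + len("TTTTTT") + len(tract) + 1  # the C of CG, 1-based
        v = parse_hgvs(f"g.{v_pos}C>A")
        rep = delta_splice_scores(
            region, v, self.NATURAL, acceptor_models, seq_origin=1000
        )
        assert rep.classification == "creates_new_ss"
        # exhaustive oracle over all windows of the mutant region
        mutant = region[: v_pos - 1001] + "A" + region[v_pos - 1000 :]
        for model in acceptor_models:
            best = max(
                model.score(SiteWindow("acceptor", mutant[i : i + 23], relaxed=True))
                for i in range(len(mutant) - 22)
                if mutant[i + 18 : i + 20] == "AG"
            )
            assert rep.deltas[model.kind].post_score == pytest.approx(best)
            assert rep.deltas[model.kind].delta == pytest.approx(
                rep.deltas[model.kind].post_score
                - rep.deltas[model.kind].pre_score
            )

    def test_strengthening_an_existing_site(self, acceptor_models):
        tract = "TCTTTCTTTGTTCCTTTCTT"  # one purine interruption
        region = "TTTTTT" + tract[:-2] + "TAG" + "GAAATTTTTT"
        # replace the G interruption (position 9 of the tract) with T
        v_pos = 1000 + 6 + 9 + 1
        v = parse_hgvs(f"g.{v_pos}G>T")
        rep = delta_splice_scores(
            region, v, self.NATURAL, acceptor_models, seq_origin=1000
        )
        assert rep.classification == "strengthens_cryptic_ss"
        assert any(d.delta > 0 for d in rep.deltas.values())

    def test_variant_outside_region_errors(self, acceptor_models):
        with pytest.raises(Exception):
            delta_splice_scores(
                "T" * 50, parse_hgvs("g.2000T>C"), self.NATURAL,
                acceptor_models, seq_origin=1000,
            )
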