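import itertools
import math

import numpy as np
import pytest
from scipy import stats

from conftest import random_profile, random_protein
from oscmine import scoring
from oscmine.alphabet import AA, BACKGROUND
from oscmine.profiles import build_profile, make_weighted_msa


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of all local paths
# ---------------------------------------------------------------------------

def enumerate_paths(hmm, query):
    """Yield the probability-odds of every local path (entry 1/L, exit 1/L).

    Paths start and end in a match state; I/D states are interior.  Emission
    odds are match_emis/background for M, 1 for I.  Written as plain
    recursion, independent of the DP implementation.
    """
    L = hmm.L
    m = len(query)
    odds = hmm.match_emis / hmm.background[None, :]
    qi = [AA.index(a) for a in query]
    t = hmm.transitions
    out = []

    def walk(state, j, k, p):
        # p includes everything up to and including the current state emission
        if state == "M":
            out.append(p / L)   # exit here
        if state == "M":
            if j < L and k < m:
                walk("M", j + 1, k + 1, p * t[j, 0] * odds[j, qi[k]])
            if k < m:
                walk("I", j, k + 1, p * t[j, 1])
            if j < L:
                walk("D", j + 1, k, p * t[j, 2])
        elif state == "I":
            if j < L and k < m:
                walk("M", j + 1, k + 1, p * t[j, 3] * odds[j, qi[k]])
            if k < m:
                walk("I", j, k + 1, p * t[j, 4])
        else:
            if j < L and k < m:
                walk("M", j + 1, k + 1, p * t[j, 5] * odds[j, qi[k]])
            if j < L:
                walk("D", j + 1, k, p * t[j, 6])

    for j0 in range(1, L + 1):
        for k0 in range(1, m + 1):
            walk("M", j0, k0, (1.0 / L) * odds[j0 - 1, qi[k0 - 1]])
    return out


class TestOracleEquivalence:
    """Viterbi/forward equal exhaustive path enumeration on small instances."""

    @pytest.mark.parametrize("L,mlen", list(itertools.product([1, 2, 3, 4], [1, 3, 6])))
    def test_all_small_profiles_and_queries(self, rng, L, mlen):
        for rep in range(3):
            hmm = random_profile(rng, L)
            query = random_protein(rng, mlen)
            path_odds = enumerate_paths(hmm, query)
            best = max(path_odds) if path_odds else 0.0
            vit = scoring.viterbi(hmm, query).score_bits
            assert np.isclose(2.0 ** vit, max(best, 1.0), rtol=1e-9)
            fwd = scoring.forward(hmm, query)
            assert np.isclose(2.0 ** fwd, 1.0 + sum(path_odds), rtol=1e-9)

    def test_forward_ge_viterbi_200_random(self, rng):
        for _ in range(200):
            hmm = random_profile(rng, int(rng.integers(1, 8)))
            q = random_protein(rng, int(rng.integers(1, 12)))
            assert scoring.forward(hmm, q) >= scoring.viterbi(hmm, q).score_bits - 1e-9

    def test_degenerate_single_path_profile(self, rng):
        # deterministic transitions and (near) deterministic emissions:
        # forward ~ viterbi
        hmm = random_profile(rng, 5)
        hmm.transitions[:, 0] = 1.0
        hmm.transitions[:, 1:3] = 0.0
        hmm.transitions[:, 3] = 1.0
        hmm.transitions[:, 4] = 0.0
        hmm.transitions[:, 5] = 1.0
        hmm.transitions[:, 6] = 0.0
        emis = np.full((5, 20), 1e-12)
        seq = "MKVLI"
        for j, a in enumerate(seq):
            emis[j, AA.index(a)] = 1.0 - 19e-12
        hmm.match_emis = emis
        v = scoring.viterbi(hmm, seq).score_bits
        f = scoring.forward(hmm, seq)
        # with local wings the all-paths sum also carries the prefix/suffix
        # truncations and the empty path, each ~20x smaller than the single
        # dominant path, so forward exceeds Viterbi by well under a quarter bit
        assert 0.0 <= f - v < 0.25


class TestViterbiSemantics:
    def test_background_profile_scores_zero(self, rng):
        hmm = random_profile(rng, 6)
        hmm.match_emis = np.tile(BACKGROUND, (6, 1))
        aln = scoring.viterbi(hmm, random_protein(rng, 10))
        assert aln.score_bits == 0.0 and aln.path == []

    def test_one_row_sharp_profile_closed_form(self):
        # profile built by hand: emission 0.99 for the row's residues
        seq = "MKVLITGAGG"
        L = len(seq)
        emis = np.full((L, 20), 0.01 / 19)
        for j, a in enumerate(seq):
            emis[j, AA.index(a)] = 0.99
        trans = np.zeros((L + 1, 7))
        trans[:, 0] = trans[:, 3] = trans[:, 5] = 1.0
        from oscmine.profiles import ProfileHMM
        hmm = ProfileHMM("sharp", L, emis, BACKGROUND.copy(), trans, BACKGROUND.copy())
        expected = sum(math.log2(0.99 / BACKGROUND[AA.index(a)]) for a in seq) \
            - 2 * math.log2(L)
        got = scoring.viterbi(hmm, seq).score_bits
        assert abs(got - expected) < 1e-6

    def test_stop_treated_as_x(self, toy_profile):
        with_stop = scoring.viterbi(toy_profile, "MKV*ITGAGGFLGSA")
        with_x = scoring.viterbi(toy_profile, "MKVXITGAGGFLGSA")
        assert np.isclose(with_stop.score_bits, with_x.score_bits)

    def test_invariant_to_flanking_residues(self, toy_profile, toy_msa):
        core = toy_msa.rows[0][1]
        s0 = scoring.viterbi(toy_profile, core).score_bits
        s1 = scoring.viterbi(toy_profile, "W" + core + "W").score_bits
        assert s1 >= s0 - 1e-9   # local alignment never hurt by flanks

    def test_traceback_score_consistency(self, rng, toy_profile, toy_msa):
        """The path re-scored by hand equals the reported Viterbi score."""
        q = toy_msa.rows[1][1]
        aln = scoring.viterbi(toy_profile, q)
        t = np.log2(toy_profile.transitions)
        esc = toy_profile.emission_scores()
        total = -math.log2(toy_profile.L)   # entry
        prev = None
        qi = [AA.index(a) for a in q]
        for (st, col, k) in aln.path:
            if st == "M":
                if prev is not None:
                    total += {"M": t[col - 1, 0], "I": t[col - 1, 3],
                              "D": t[col - 1, 5]}[prev[0]]
                total += esc[col - 1, qi[k]]
            elif st == "I":
                total += t[col, 1] if prev[0] == "M" else t[col, 4]
            else:
                total += t[col - 1, 2] if prev[0] == "M" else t[col - 1, 6]
            prev = (st, col)
        total += -math.log2(toy_profile.L)  # exit
        assert abs(total - aln.score_bits) < 1e-6


class TestBitscore:
    def test_background_profile_near_zero(self, rng):
        # every path has emission odds 1, so the all-paths sum is bounded by
        # the start/stop multiplicity: a few bits at most, negligible against
        # any cascade threshold (and the Viterbi score is exactly 0)
        hmm = random_profile(rng, 6)
        hmm.match_emis = np.tile(BACKGROUND, (6, 1))
        q = random_protein(rng, 12)
        b = scoring.bitscore(hmm, q)
        assert 0.0 <= b < np.log2(1.0 + 2.0 * len(q))
        assert scoring.viterbi(hmm, q).score_bits == 0.0

    def test_sharp_700_column_consensus_exceeds_500(self, rng):
        L = 700
        cons = random_protein(rng, L)
        emis = np.full((L, 20), 0.1 / 19)
        for j, a in enumerate(cons):
            emis[j, AA.index(a)] = 0.9
        trans = np.zeros((L + 1, 7))
        trans[:, 0] = 0.98
        trans[:, 1] = trans[:, 2] = 0.01
        trans[:, 3] = trans[:, 5] = 0.9
        trans[:, 4] = trans[:, 6] = 0.1
        from oscmine.profiles import ProfileHMM
        hmm = ProfileHMM("sharp700", L, emis, BACKGROUND.copy(), trans,
                         BACKGROUND.copy())
        assert scoring.bitscore(hmm, cons) > 500.0

    def test_monotone_decay_under_randomization(self, rng, toy_profile, toy_msa):
        base = toy_msa.rows[0][1]
        means = []
        for k in (0, 5, 10, 15):
            vals = []
            for _ in range(50):
                s = list(base)
                pos = rng.choice(len(s), size=k, replace=False)
                for p in pos:
                    s[p] = AA[rng.integers(20)]
                vals.append(scoring.bitscore(toy_profile, "".join(s)))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2] > means[3]


class TestCalibration:
    def test_gumbel_recovery_within_5pct(self):
        rng = np.random.default_rng(77)
        mu, lam = 10.0, 0.7
        scores = stats.gumbel_r.rvs(loc=mu, scale=1 / lam, size=5000,
                                    random_state=rng)
        mu_hat, lam_hat = scoring.fit_gumbel(scores)
        assert abs(mu_hat - mu) / mu < 0.05
        assert abs(lam_hat - lam) / lam < 0.05

    def test_deterministic_under_seed(self, toy_profile):
        a = scoring.calibrate_evalue(toy_profile, n_decoys=60, decoy_len=30, seed=5)
        b = scoring.calibrate_evalue(toy_profile, n_decoys=60, decoy_len=30, seed=5)
        assert a == b

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            scoring.fit_gumbel(np.full(100, 3.0))

    def test_needs_50_decoys(self, toy_profile):
        with pytest.raises(ValueError, match="at least 50"):
            scoring.calibrate_evalue(toy_profile, n_decoys=10)


class TestEvalue:
    @pytest.fixture(scope="class")
    def calibrated(self, toy_profile):
        scoring.calibrate_evalue(toy_profile, n_decoys=100, decoy_len=30, seed=2)
        return toy_profile

    def test_linear_in_db_size(self, calibrated):
        e1 = scoring.evalue(calibrated, 8.0, 10_000)
        e2 = scoring.evalue(calibrated, 8.0, 20_000)
        assert np.isclose(e2, 2.0 * e1)

    def test_closed_form_at_mu(self, calibrated):
        mu, lam = calibrated.calibration
        decoy_len = calibrated.calibration_decoy_len
        e = scoring.evalue(calibrated, mu, 10_000)
        assert np.isclose(e, (10_000 / decoy_len) * (1 - math.exp(-1.0)), rtol=1e-9)

    def test_limit_zero_and_monotone(self, calibrated):
        assert scoring.evalue(calibrated, 1e6, 10_000) == pytest.approx(0.0, abs=1e-12)
        es = [scoring.evalue(calibrated, s, 10_000) for s in (0, 5, 10, 20, 40)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_uncalibrated_raises(self, rng):
        hmm = random_profile(rng, 4)
        with pytest.raises(ValueError, match="not calibrated"):
            scoring.evalue(hmm, 10.0, 1000)

    def test_percentile_consistency(self, calibrated):
        """E-value at the 95th percentile decoy score is ~0.05 x db factor."""
        mu, lam = calibrated.calibration
        s95 = stats.gumbel_r.ppf(0.95, loc=mu, scale=1 / lam)
        e = scoring.evalue(calibrated, s95, calibrated.calibration_decoy_len)
        assert np.isclose(e, 0.05, rtol=1e-9)
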