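import itertools

import numpy as np
import pytest

from mirmotif import (
    AlignmentScoring,
    ExpressionProfile,
    MatureSequence,
    ProfileSet,
    TimeGrid,
    ks_two_sample,
    nw_score,
    pair_analysis,
    quantile_curve,
)
from mirmotif.seqsim import iter_pairs

# Mature sequences of two miRNAs known to differ by a single substitution.
MIR_103 = "AGCAGCAUUGUACAGGGCUAUGA"
MIR_107 = "AGCAGCAUUGUACAGGGCUAUCA"


def nw_dp(s1, s2, match=1.0, mismatch=-1.0, gap=-2.0):
    """Independent quadratic DP oracle for global alignment with linear gaps."""
    n, m = len(s1), len(s2)
    D = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = i * gap
    for j in range(1, m + 1):
        D[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if s1[i - 1] == s2[j - 1] else mismatch
            D[i][j] = max(D[i - 1][j - 1] + sub, D[i - 1][j] + gap, D[i][j - 1] + gap)
    return D[n][m]


def ks_brute(a, b):
    """Sup of the ECDF gap evaluated over the pooled sample points."""
    a, b = np.sort(a), np.sort(b)
    pooled = np.concatenate([a, b])
    gaps = [
        abs(np.searchsorted(a, x, side="right") / len(a)
            - np.searchsorted(b, x, side="right") / len(b))
        for x in pooled
    ]
    return max(gaps)


class TestSequences:
    def test_normalization(self):
        seq = MatureSequence("x", "acgt")
        assert seq.sequence == "ACGU"

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            MatureSequence("x", "ACGX")
        with pytest.raises(ValueError):
            MatureSequence("x", "")


class TestNeedlemanWunsch:
    def test_self_alignment(self):
        assert nw_score(MIR_103, MIR_103) == len(MIR_103)

    def test_known_single_substitution_pair(self):
        # 22 matches and 1 mismatch under (+1, -1, -2)
        assert nw_score(MIR_103, MIR_107) == 21.0
        assert nw_score(MIR_103, MIR_107) == nw_dp(MIR_103, MIR_107)

    def test_all_gap_alignment(self):
        # the empty-vs-length-L alignment is all gaps and scores L * gap
        scoring = AlignmentScoring()
        assert nw_dp("", "ACGU") == 4 * scoring.gap
        with pytest.raises(ValueError):
            nw_score("", "ACGU")  # empty sequences are rejected upstream

    def test_symmetry_and_oracle_on_random_sequences(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(10):
            s1 = "".join(rng.choice(bases, size=rng.integers(5, 25)))
            s2 = "".join(rng.choice(bases, size=rng.integers(5, 25)))
            assert nw_score(s1, s2) == nw_score(s2, s1)
            assert nw_score(s1, s2) == nw_dp(s1, s2)

    def test_bad_scoring_rejected(self):
        with pytest.raises(ValueError):
            AlignmentScoring(match=-1.0, mismatch=0.0)


def _profile_set(rng, ids, grid=None):
    grid = grid or TimeGrid(tuple(range(8)))
    return ProfileSet(grid, (
        ExpressionProfile(i, "miRNA", rng.normal(size=8), grid) for i in ids
    ))


class TestPairAnalysis:
    def test_pair_enumeration(self):
        assert len(list(iter_pairs(range(266)))) == 266 * 265 // 2
        assert len(list(iter_pairs("abc"))) == 3

    def test_groups_partition_pairs(self, rng):
        ids = [f"m{i}" for i in range(6)]
        profiles = _profile_set(rng, ids)
        bases = np.array(list("ACGU"))
        seqs = [MatureSequence(i, "".join(rng.choice(bases, size=22))) for i in ids]
        table = pair_analysis(profiles, seqs, nwa_threshold=10.0)
        assert len(table) == 15
        assert (table.group.isin(["High", "Low"])).all()
        assert ((table.nwa > 10.0) == (table.group == "High")).all()

    def test_missing_sequence_reported(self, rng):
        profiles = _profile_set(rng, ["m0", "m1"])
        with pytest.raises(KeyError, match="m1"):
            pair_analysis(profiles, [MatureSequence("m0", "ACGU" * 5)])


class TestKS:
    def test_identical_samples(self):
        stat, _ = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)

    def test_disjoint_supports(self):
        stat, p = ks_two_sample([0.0, 1.0, 2.0], [10.0, 11.0])
        assert stat == pytest.approx(1.0)
        assert p < 0.2

    def test_matches_bruteforce_ecdf(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 7))
            b = rng.normal(size=rng.integers(2, 7))
            stat, _ = ks_two_sample(a, b)
            assert stat == pytest.approx(ks_brute(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestQuantiles:
    def test_extremes_and_constant(self, rng):
        x = rng.normal(size=20)
        lo, hi = quantile_curve(x, [0.0, 1.0])
        assert lo == x.min() and hi == x.max()
        np.testing.assert_allclose(quantile_curve(np.full(5, 2.0), [0.1, 0.9]), 2.0)

    def test_matches_order_statistics(self):
        x = np.array([5.0, 1.0, 3.0, 2.0, 4.0])
        probs = np.linspace(0, 1, 5)
        np.testing.assert_allclose(quantile_curve(x, probs), [1, 2, 3, 4, 5])


def test_sequence_similar_mirnas_have_closer_profiles(rng):
    """Planted families: similar sequences + correlated profiles dominate.

    GroupHigh (similar sequences) must sit stochastically below GroupLow in
    expression distance: every GroupHigh quantile <= the GroupLow quantile.
    """
    grid = TimeGrid(tuple(range(10)))
    bases = np.array(list("ACGU"))
    profiles = ProfileSet(grid)
    sequences = []
    for fam in range(6):
        template_seq = rng.choice(bases, size=22)
        template_prof = rng.normal(size=10)
        for member in range(4):
            seq = template_seq.copy()
            for pos in rng.choice(22, size=2, replace=False):  # 2 point mutations
                seq[pos] = rng.choice(bases)
            sid = f"f{fam}m{member}"
            sequences.append(MatureSequence(sid, "".join(seq)))
            values = template_prof + rng.normal(0, 0.1, size=10)
            profiles.add(ExpressionProfile(sid, "miRNA", values, grid))
    table = pair_analysis(profiles, sequences, nwa_threshold=10.0)
    high = table.loc[table.group == "High", "distance"].to_numpy()
    low = table.loc[table.group == "Low", "distance"].to_numpy()
    assert high.size > 10 and low.size > 10
    probs = np.linspace(0.05, 0.95, 19)
    assert np.all(quantile_curve(high, probs) <= quantile_curve(low, probs))
    stat, p = ks_two_sample(high, low)
    assert p < 1e-6
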