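import math
import random
from itertools import combinations

import numpy as np
import pytest

from fastools.alignment_sites import AlignmentMatrix
from fastools.fixtures import coalescent_sample
from fastools.popgen import (
    WindowSpec,
    basic_counts,
    ewens_EK,
    fu_li_Dstar,
    fu_li_Fstar,
    harmonic,
    mean_pairwise,
    sliding_windows,
    summarize,
    tajima_D,
    usable_columns,
    watterson,
)
from fastools.record_io import SequenceRecord


def aln(*seqs):
    return AlignmentMatrix(
        [SequenceRecord(f"r{i}", "", s) for i, s in enumerate(seqs)]
    )


def random_alignment(rng, n=None, width=None, alphabet="ACGT"):
    n = n or rng.randrange(2, 9)
    width = width or rng.randrange(1, 51)
    return aln(*(
        "".join(rng.choice(alphabet) for _ in range(width)) for _ in range(n)
    ))


class TestUsableColumns:
    def test_gap_free_strict_all_usable(self):
        assert usable_columns(aln("ACGT", "ACGT")) == [1, 2, 3, 4]

    def test_complete_deletion_drops_gapped_column(self):
        assert usable_columns(aln("AC-T", "ACGT")) == [1, 2, 4]

    def test_ambiguity_also_dropped(self):
        assert usable_columns(aln("ACNT", "ACGT")) == [1, 2, 4]

    def test_as_is_keeps_everything(self):
        assert usable_columns(aln("AC-N", "ACGT"), "as_is") == [1, 2, 3, 4]


class TestBasicCounts:
    def test_worked_alignment(self, worked_alignment):
        n, k, S, s, eta, eta_S = basic_counts(worked_alignment)
        assert (n, k, S, s, eta, eta_S) == (3, 3, 2, 0.5, 2, 2)

    def test_identical_rows(self):
        n, k, S, s, eta, eta_S = basic_counts(aln("ACGT", "ACGT"))
        assert (k, S, eta) == (1, 0, 0)

    def test_triallelic_column(self):
        # states {A,A,T,G}: 3 states -> eta += 2; two singletons (T, G)
        n, k, S, s, eta, eta_S = basic_counts(aln("A", "A", "T", "G"))
        assert (S, eta, eta_S) == (1, 2, 2)

    def test_eta_at_least_S_and_equal_when_biallelic(self):
        rng = random.Random(7)
        for _ in range(30):
            a = random_alignment(rng)
            _, _, S, _, eta, _ = basic_counts(a)
            assert eta >= S
            b = random_alignment(rng, alphabet="AT")
            _, _, S2, _, eta2, _ = basic_counts(b)
            assert eta2 == S2


class TestPairwise:
    def test_worked_alignment(self, worked_alignment):
        Pi, pi = mean_pairwise(worked_alignment)
        assert Pi == pytest.approx(4 / 3)
        assert pi == pytest.approx(1 / 3)

    def test_identical_rows_zero(self):
        assert mean_pairwise(aln("AC", "AC", "AC"))[0] == 0

    def test_two_rows_is_plain_distance(self):
        Pi, _ = mean_pairwise(aln("AAAA", "ATAT"))
        assert Pi == 2

    def test_matches_allele_frequency_formula(self):
        """Independent oracle: Pi from per-column allele frequencies."""
        rng = random.Random(3)
        for _ in range(500):
            a = random_alignment(rng, width=rng.randrange(1, 51))
            cols = usable_columns(a)
            n = a.n
            pairs = n * (n - 1) / 2
            expected = 0.0
            for j in cols:
                col = a.column(j).upper()
                counts = {}
                for ch in col:
                    counts[ch] = counts.get(ch, 0) + 1
                same = sum(c * (c - 1) / 2 for c in counts.values())
                expected += (pairs - same) / pairs
            Pi, _ = mean_pairwise(a, cols)
            assert Pi == pytest.approx(expected)

    def test_invariant_under_row_order(self, worked_alignment):
        rows = list(worked_alignment.rows)
        shuffled = AlignmentMatrix([rows[2], rows[0], rows[1]])
        assert mean_pairwise(shuffled) == mean_pairwise(worked_alignment)
        assert basic_counts(shuffled)[1:] == basic_counts(worked_alignment)[1:]


class TestEstimators:
    def test_watterson_n2(self):
        assert watterson(3, 2, 100) == (3.0, 0.03)

    def test_watterson_n3(self):
        per_locus, _ = watterson(2, 3, 4)
        assert per_locus == pytest.approx(2 / 1.5)

    def test_watterson_no_variation(self):
        assert watterson(0, 5, 100) == (0.0, 0.0)

    def test_ewens_limits(self):
        assert ewens_EK(10, 0.0) == 1.0
        assert ewens_EK(1, 3.0) == 1.0
        assert ewens_EK(2, 1.0) == pytest.approx(1.5)

    def test_tajima_worked_zero(self, worked_alignment):
        Pi, _ = mean_pairwise(worked_alignment)
        assert tajima_D(Pi, 2, 3) == 0.0

    def test_tajima_na_when_no_segregating_sites(self):
        assert tajima_D(0.0, 0, 10) is None

    def test_fu_li_worked_zero(self, worked_alignment):
        assert fu_li_Dstar(2, 2, 3) == 0.0
        Pi, _ = mean_pairwise(worked_alignment)
        assert fu_li_Fstar(Pi, 2, 2, 3) == 0.0

    def test_fu_li_na_cases(self):
        assert fu_li_Dstar(0, 0, 10) is None
        assert fu_li_Fstar(1.0, 0, 0, 10) is None
        assert fu_li_Dstar(3, 1, 2) is None  # below minimum sample size

    def test_matches_tskit_on_simulated_data(self):
        """Pi, S and Tajima's D agree with tskit on msprime output."""
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(samples=5, ploidy=2, sequence_length=5000,
                                  population_size=1000, random_seed=7)
        mts = msprime.sim_mutations(ts, rate=5e-7, random_seed=7,
                                    model=msprime.BinaryMutationModel())
        G = mts.genotype_matrix()
        rows = [
            SequenceRecord(f"s{i}", "",
                           "".join("T" if g else "A" for g in G[:, i]))
            for i in range(G.shape[1])
        ]
        a = AlignmentMatrix(rows)
        cols = usable_columns(a)
        n, _, S, _, _, _ = basic_counts(a, cols)
        Pi, _ = mean_pairwise(a, cols)
        assert Pi == pytest.approx(mts.diversity(span_normalise=False))
        assert S == int(mts.segregating_sites(span_normalise=False))
        assert tajima_D(Pi, S, n) == pytest.approx(mts.Tajimas_D())


class TestNeutralCalibration:
    def test_coalescent_means_near_neutral_expectation(self):
        """Means of S, D, D*, F* over neutral replicates match theory."""
        rng = np.random.default_rng(20090)
        n, theta, reps = 10, 5.0, 2000
        S_vals, D_vals, Ds_vals, Fs_vals, Pi_vals = [], [], [], [], []
        for _ in range(reps):
            a = coalescent_sample(n, theta, rng)
            cols = list(range(1, a.width + 1))
            _, _, S, _, eta, eta_S = basic_counts(a, cols)
            Pi, _ = mean_pairwise(a, cols)
            S_vals.append(S)
            Pi_vals.append(Pi)
            d = tajima_D(Pi, S, n)
            if d is not None:
                D_vals.append(d)
            ds = fu_li_Dstar(eta, eta_S, n)
            if ds is not None:
                Ds_vals.append(ds)
            fs = fu_li_Fstar(Pi, eta, eta_S, n)
            if fs is not None:
                Fs_vals.append(fs)
        expected_S = theta * harmonic(n - 1)
        assert np.mean(S_vals) == pytest.approx(expected_S, rel=0.10)
        assert abs(np.mean(D_vals)) < 0.2
        assert abs(np.mean(Ds_vals)) < 0.25
        assert abs(np.mean(Fs_vals)) < 0.25
        # theta_W per site and pi agree in expectation
        mean_thetaW = np.mean(S_vals) / harmonic(n - 1)
        assert mean_thetaW / np.mean(Pi_vals) == pytest.approx(1.0, rel=0.10)


class TestSummaryAndWindows:
    def test_worked_summary(self, worked_alignment):
        s = summarize(worked_alignment)
        assert (s.n, s.k, s.S, s.eta, s.eta_S) == (3, 3, 2, 2, 2)
        assert s.s == 0.5
        assert s.Pi == pytest.approx(4 / 3)
        assert s.theta_W == pytest.approx(4 / 3)
        assert s.D == 0.0 and s.Dstar == 0.0 and s.Fstar == 0.0

    def test_na_rendered_not_zero(self):
        s = summarize(aln("ACGT", "ACGT"))
        row = dict(zip(s.FIELDS, s.row()))
        assert row["D"] == "NA" and row["Dstar"] == "NA"

    def test_window_starts(self):
        rng = random.Random(0)
        a = random_alignment(rng, n=4, width=200)
        header, rows = sliding_windows(a, WindowSpec(100, 25, ("d",)))
        assert [r[0] for r in rows] == [1, 26, 51, 76, 101]
        assert [r[1] for r in rows] == [100, 125, 150, 175, 200]

    def test_full_width_window_equals_whole_alignment(self):
        rng = random.Random(1)
        a = random_alignment(rng, n=5, width=60)
        header, rows = sliding_windows(a, WindowSpec(60, 10, ("d", "p", "w", "s")))
        assert len(rows) == 1
        s = summarize(a)
        d, p, w, S = rows[0][2:]
        assert d == s.D
        assert p == s.pi
        assert w == s.theta_W_per_site
        assert S == s.S

    def test_window_wider_than_alignment_is_error(self):
        from fastools.errors import UsageError

        with pytest.raises(UsageError):
            sliding_windows(aln("AC", "AC"), WindowSpec(5, 1))

    def test_window_spec_parsing(self):
        spec = WindowSpec.parse("100:25:d")
        assert (spec.width, spec.step, spec.stat_codes) == (100, 25, ("d",))
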