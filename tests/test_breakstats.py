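import numpy as np
import pytest
from scipy import stats

from lsrseq.breakstats import (
    StructureSummary,
    breakpoint_map,
    chi_square_structures,
    compare_observed_vs_null,
    distance_to_nearest,
    expected_random_distance,
    summarize_structures,
)
from lsrseq.quantify import UniqueJunction
from lsrseq.reference import ReferenceRegion, ReferenceSet

from .oracles import expected_distance_enumeration, mannwhitney_exact_p, pearson_chi2


def _uj(db=10, ab=20, structure="blunt", mh=0, ins="", acceptor="A", jtype="direct"):
    return UniqueJunction(
        key=("Smu", db, acceptor, ab, ins, jtype, None),
        read_count=1,
        structure=structure,
        mh_len=mh,
    )


class TestDistance:
    def test_inside_occurrence(self):
        assert distance_to_nearest(5, [(2, 8)]) == 0

    def test_boundary_is_zero(self):
        assert distance_to_nearest(8, [(2, 8)]) == 0

    def test_left_of_single(self):
        assert distance_to_nearest(0, [(10, 14)]) == 10

    def test_min_over_edges(self):
        assert distance_to_nearest(9, [(2, 4), (12, 16)]) == 3

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            distance_to_nearest(1, [])


class TestExpectedRandom:
    def test_tiled_interval_zero(self):
        mean, _ = expected_random_distance(None, [(0, 10)], (0, 10))
        assert mean == 0.0

    def test_enumerated_example(self):
        mean, profile = expected_random_distance(None, [(2, 3)], (0, 4))
        assert list(profile) == [2, 1, 0, 0, 1]
        assert mean == pytest.approx(0.8)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            length = int(rng.integers(50, 300))
            n_occ = int(rng.integers(1, 8))
            occ = []
            for _ in range(n_occ):
                s = int(rng.integers(0, length - 4))
                occ.append((s, s + int(rng.integers(2, 5))))
            mean, profile = expected_random_distance(None, occ, (0, length))
            o_mean, o_vals = expected_distance_enumeration(occ, 0, length)
            assert list(profile) == o_vals
            assert mean == o_mean

    def test_monte_carlo_agreement(self, rng):
        occ = [(40, 44), (200, 202), (333, 337)]
        mean, profile = expected_random_distance(None, occ, (0, 500))
        draws = rng.integers(0, 501, size=100_000)
        samples = profile[draws]
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(samples.mean() - mean) <= 3 * se

    def test_interval_outside_region(self):
        region = ReferenceRegion("r", "ACGT" * 5, "acceptor")
        with pytest.raises(ValueError):
            expected_random_distance(region, [(0, 2)], (0, 100))


class TestObservedVsNull:
    def test_observed_all_zero(self):
        profile = np.array([3, 4, 5, 6, 7, 0, 1], dtype=float)
        stat, p, diff = compare_observed_vs_null([0] * 20, profile)
        assert diff < 0
        assert p < 0.01

    def test_observed_equals_null(self):
        profile = np.array([0, 1, 2, 3, 4], dtype=float)
        _, _, diff = compare_observed_vs_null(list(profile), profile)
        assert diff == 0.0

    def test_exact_permutation_small(self):
        obs = [0, 1, 2]
        null = np.array([3, 4, 5, 6, 7], dtype=float)
        _, p, _ = compare_observed_vs_null(obs, null)
        assert p == pytest.approx(mannwhitney_exact_p(obs, list(null)), abs=1e-9)


class TestStructureSummary:
    def test_all_blunt(self):
        s = summarize_structures([_uj() for _ in range(10)])
        assert s.percentages["blunt"] == 100.0
        assert s.mean_mh_len is None
        assert s.mean_insertion_len is None

    def test_mix_percentages(self):
        uniques = (
            [_uj(db=i, structure="blunt") for i in range(2)]
            + [_uj(db=10 + i, structure="microhomology", mh=3) for i in range(5)]
            + [_uj(db=20 + i, structure="insertion", ins="ACG") for i in range(3)]
        )
        s = summarize_structures(uniques)
        assert s.percentages == {"blunt": 20.0, "microhomology": 50.0, "insertion": 30.0}
        assert s.mean_mh_len == 3.0
        assert s.mean_insertion_len == 3.0

    def test_percentages_sum_100(self, rng):
        structures = ["blunt", "microhomology", "insertion"]
        uniques = []
        for i in range(200):
            st = structures[int(rng.integers(3))]
            uniques.append(
                _uj(db=i, structure=st, mh=1 if st == "microhomology" else 0,
                    ins="A" if st == "insertion" else "")
            )
        s = summarize_structures(uniques)
        assert sum(s.percentages.values()) == pytest.approx(100.0, abs=0.01)


class TestChiSquare:
    def _summary(self, blunt, mh, ins):
        uniques = (
            [_uj(db=i, structure="blunt") for i in range(blunt)]
            + [_uj(db=100 + i, structure="microhomology", mh=2) for i in range(mh)]
            + [_uj(db=200 + i, structure="insertion", ins="A") for i in range(ins)]
        )
        return summarize_structures(uniques)

    def test_identical_distributions(self):
        a = self._summary(10, 20, 30)
        chi2, df, p = chi_square_structures(a, a)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        a = self._summary(10, 20, 0)
        b = self._summary(20, 10, 0)
        chi2, df, p = chi_square_structures(a, b)
        assert df == 1
        assert chi2 == pytest.approx(20 / 3, abs=1e-9)

    def test_formula_oracle_random_tables(self, rng):
        for _ in range(100):
            a = self._summary(*(int(x) for x in rng.integers(1, 50, 3)))
            b = self._summary(*(int(x) for x in rng.integers(1, 50, 3)))
            chi2, df, _ = chi_square_structures(a, b)
            table = [
                [a.counts[c] for c in ("blunt", "microhomology", "insertion")],
                [b.counts[c] for c in ("blunt", "microhomology", "insertion")],
            ]
            o_chi2, o_df = pearson_chi2(table)
            assert chi2 == pytest.approx(o_chi2)
            assert df == o_df


class TestBreakpointMap:
    def test_single_junction_single_bin(self, regions):
        uniques = [_uj(db=120, ab=70, acceptor="RR2_hs4")]
        out = breakpoint_map(uniques, regions, bin_width=50)
        hist = out["histograms"]["Smu"]
        assert hist.sum() == 1
        assert hist[2] == 1
        assert out["histograms"]["RR2_hs4"][1] == 1
        assert out["donor_acceptor_counts"]["RR2_hs4"].sum() == 1

    def test_totals_conserved(self, regions, rng):
        uniques = [
            _uj(db=int(rng.integers(0, 1200)), ab=int(rng.integers(0, 900)),
                acceptor="RR1_hs4")
            for _ in range(250)
        ]
        out = breakpoint_map(uniques, regions)
        assert out["histograms"]["Smu"].sum() == 250
        assert out["histograms"]["RR1_hs4"].sum() == 250

    def test_uniform_breaks_flat(self, regions, rng):
        # goodness-of-fit not rejected at alpha=0.01 for uniform breaks
        donor_len = len(regions["Smu"].sequence)
        uniques = [
            _uj(db=int(rng.integers(0, donor_len)), ab=int(rng.integers(0, 900)),
                acceptor="RR1_hs4")
            for _ in range(2000)
        ]
        out = breakpoint_map(uniques, regions, bin_width=100)
        hist = out["histograms"]["Smu"]
        _, p = stats.chisquare(hist)
        assert p > 0.01
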