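"""Microsatellite diversity, HWE/LD screening and F_ST."""

import numpy as np
import pytest

from divcompare.errors import EmptyLocusError, InsufficientSampleError
from divcompare.msat_stats import (
    allele_frequencies,
    fst_estimate,
    hwe_test,
    ld_permutation_test,
    locus_diversity,
    locus_qc_filter,
    missing_and_deficit_warnings,
)

from conftest import make_msat


def _hwe_genotypes(counts):
    """Genotype rows from a {(a, b): count} table."""
    rows = []
    for (a, b), c in counts.items():
        rows += [[(a, b)]] * c
    return make_msat(rows, loci=["L1"])


class TestAlleleFrequencies:
    def test_worked_example(self):
        ds = make_msat([[(150, 152)], [(150, 150)]])
        assert allele_frequencies(ds, "L1") == {150: 0.75, 152: 0.25}

    def test_all_missing_raises(self):
        ds = make_msat([[None], [None]])
        with pytest.raises(EmptyLocusError):
            allele_frequencies(ds, "L1")

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            rows = [[(int(rng.integers(1, 8)), int(rng.integers(1, 8)))] for _ in range(n)]
            ds = make_msat(rows)
            assert sum(allele_frequencies(ds, "L1").values()) == pytest.approx(1.0)


class TestLocusDiversity:
    def test_monomorphic(self):
        ds = make_msat([[(5, 5)], [(5, 5)], [(5, 5)]])
        ld = locus_diversity(ds, "L1")
        assert (ld.Ho, ld.He, ld.Ae, ld.shannon) == (0.0, 0.0, 1.0, 0.0)

    def test_worked_frequencies(self):
        # freqs 0.5, 0.25, 0.25 over 8 copies
        ds = make_msat([[(1, 1)], [(1, 1)], [(2, 2)], [(3, 3)]])
        ld = locus_diversity(ds, "L1")
        assert ld.Ae == pytest.approx(8 / 3)
        assert ld.shannon == pytest.approx(1.0397, abs=1e-4)
        assert ld.He == pytest.approx(1 - 0.375)

    def test_he_ae_consistency(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            rows = [
                [(int(rng.integers(1, 6)), int(rng.integers(1, 6)))]
                for _ in range(int(rng.integers(3, 40)))
            ]
            ld = locus_diversity(make_msat(rows), "L1")
            assert ld.He == pytest.approx(1 - 1 / ld.Ae)
            assert 1 <= ld.Ae <= ld.Na

    def test_unbiased_variant_larger(self):
        ds = make_msat([[(1, 2)], [(1, 1)], [(2, 2)]])
        plain = locus_diversity(ds, "L1").He
        unbiased = locus_diversity(ds, "L1", unbiased_he=True).He
        assert unbiased > plain


class TestHWE:
    def test_perfect_hwe_chi2_zero(self):
        ds = _hwe_genotypes({(1, 1): 25, (1, 2): 50, (2, 2): 25})
        assert hwe_test(ds, "L1") == pytest.approx(1.0)

    def test_extreme_heterozygote_deficit(self):
        ds = _hwe_genotypes({(1, 1): 50, (2, 2): 50})
        assert hwe_test(ds, "L1") < 1e-10

    def test_monomorphic_not_applicable(self):
        ds = _hwe_genotypes({(1, 1): 30})
        assert hwe_test(ds, "L1") is None

    def test_mc_matches_chisq_direction(self):
        ds = _hwe_genotypes({(1, 1): 20, (2, 2): 20})
        p = hwe_test(ds, "L1", method="mc", n_mc=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_mc_reproducible(self):
        ds = _hwe_genotypes({(1, 1): 8, (1, 2): 4, (2, 2): 8})
        p1 = hwe_test(ds, "L1", method="mc", n_mc=199, seed=7)
        p2 = hwe_test(ds, "L1", method="mc", n_mc=199, seed=7)
        assert p1 == p2


class TestLD:
    def _paired_dataset(self, rng, n=40, copy=False):
        rows = []
        for _ in range(n):
            g1 = tuple(sorted(rng.integers(1, 4, size=2)))
            g2 = g1 if copy else tuple(sorted(rng.integers(1, 4, size=2)))
            rows.append([g1, g2])
        return make_msat(rows, loci=["A", "B"])

    def test_perfect_association_floor(self):
        ds = self._paired_dataset(np.random.default_rng(1), copy=True)
        p = ld_permutation_test(ds, "A", "B", n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_determinism(self):
        ds = self._paired_dataset(np.random.default_rng(2))
        p1 = ld_permutation_test(ds, "A", "B", n_perm=200, seed=5)
        p2 = ld_permutation_test(ds, "A", "B", n_perm=200, seed=5)
        assert p1 == p2

    def test_independent_loci_not_extreme(self):
        rng = np.random.default_rng(3)
        ps = [
            ld_permutation_test(
                self._paired_dataset(rng), "A", "B", n_perm=99, seed=k
            )
            for k in range(20)
        ]
        # under independence p should not pile up at the floor
        assert np.mean(np.array(ps) <= 0.05) < 0.5
        assert np.mean(ps) > 0.2


class TestFst:
    def test_identical_groups_zero(self):
        rows = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)], [(1, 1)], [(2, 2)]]
        ds = make_msat(rows, populations=["X"] * 3 + ["Y"] * 3)
        assert fst_estimate(ds).mean == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_is_one(self):
        rows = [[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]]
        ds = make_msat(rows, populations=["X", "X", "Y", "Y"])
        assert fst_estimate(ds).mean == pytest.approx(1.0)

    def test_monotone_in_frequency_shift(self):
        values = []
        for extra in (0, 4, 8, 12):
            x_rows = [[(1, 1)]] * 10 + [[(2, 2)]] * 10
            y_rows = [[(1, 1)]] * (10 - extra // 2) + [[(2, 2)]] * (10 + extra // 2)
            ds = make_msat(x_rows + y_rows, populations=["X"] * 20 + ["Y"] * 20)
            values.append(fst_estimate(ds).mean)
        assert values == sorted(values)

    def test_weir_cockerham_identical_groups_near_zero(self):
        rows = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)], [(1, 1)], [(2, 2)]]
        ds = make_msat(rows, populations=["X"] * 3 + ["Y"] * 3)
        wc = fst_estimate(ds, estimator="weir-cockerham").mean
        assert wc <= 0.05  # unbiased estimator scatters around 0

    def test_requires_two_groups(self):
        ds = make_msat([[(1, 2)], [(1, 1)]])
        with pytest.raises(InsufficientSampleError):
            fst_estimate(ds)


class TestQcFilter:
    def test_no_flags_retains_all(self):
        ds = make_msat([[(1, 2), (3, 3)], [(1, 1), (3, 4)]])
        retained, dropped = locus_qc_filter(
            ds, {("L1", "X"): 0.5, ("L2", "X"): 0.9}
        )
        assert retained == ["L1", "L2"] and dropped == {}

    def test_two_of_25_flagged_leaves_23(self):
        loci = [f"L{k:02d}" for k in range(25)]
        ds = make_msat([[(1, 2)] * 25, [(1, 1)] * 25], loci=loci)
        results = {(l, pop): 0.5 for l in loci for pop in ("X", "Y")}
        results[("L03", "X")] = 1e-9
        results[("L17", "X")] = 1e-9
        results[("L17", "Y")] = 1e-9
        retained, dropped = locus_qc_filter(ds, results)
        assert len(retained) == 23
        assert set(dropped) == {"L03", "L17"}

    def test_alpha_zero_retains_all(self):
        ds = make_msat([[(1, 2)], [(1, 1)]])
        retained, _ = locus_qc_filter(ds, {("L1", "X"): 1e-300}, alpha=0.0)
        assert retained == ["L1"]


def test_deficit_warning_emitted():
    ds = _hwe_genotypes({(1, 1): 50, (2, 2): 50})
    warnings = missing_and_deficit_warnings(ds)
    assert any("deficit" in w for w in warnings)
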