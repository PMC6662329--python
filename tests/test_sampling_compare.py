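"""Sampling tiers, matched draws and the comparison tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divcompare.errors import CapacityError, InsufficientSampleError
from divcompare.sampling_compare import (
    SamplingPlan,
    compare_populations,
    composition_of,
    conservative_match,
    disjoint_partition,
    paired_t_over_loci,
    sex_ratio_chisq,
    two_sample_t,
)
from divcompare.synthetic_data import (
    default_partition,
    paper_like_config,
    simulate_msat,
    simulate_population,
)
from divcompare.io_formats import MsatDataset, PhasedAlignment


def _metadata(rows):
    return pd.DataFrame(rows, columns=["id", "population", "sex", "age_class"])


class TestConservativeMatch:
    def test_singleton_reference_three_disjoint_draws(self):
        meta = _metadata(
            [[f"d{i}", "X", "female", "adult"] for i in range(1, 4)]
        )
        ref = {"age_class": {"adult": 1}, "sex": {"female": 1}}
        draws = conservative_match(meta, ref, n_draws=3, seed=0)
        assert sorted(x for d in draws for x in d) == ["d1", "d2", "d3"]
        assert all(len(d) == 1 for d in draws)

    def test_capacity_error_names_category(self):
        meta = _metadata(
            [[f"d{i}", "X", "female", "adult"] for i in range(1, 4)]
        )
        ref = {"age_class": {"adult": 1}, "sex": {"female": 1}}
        with pytest.raises(CapacityError, match="adult"):
            conservative_match(meta, ref, n_draws=4, seed=0)

    def test_draws_reproduce_reference_histograms(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(300):
            rows.append(
                [
                    f"d{i}",
                    "X",
                    rng.choice(["male", "female"], p=[0.6, 0.4]),
                    rng.choice(["calf", "juvenile", "adult"], p=[0.1, 0.3, 0.6]),
                ]
            )
        meta = _metadata(rows)
        ref = {
            "age_class": {"calf": 2, "juvenile": 15, "adult": 38},
            "sex": {"male": 32, "female": 23},
        }
        draws = conservative_match(meta, ref, n_draws=3, seed=1)
        assert len({x for d in draws for x in d}) == 3 * 55  # disjoint
        for d in draws:
            sub = meta[meta["id"].isin(d)]
            comp = composition_of(sub)
            assert comp["age_class"] == ref["age_class"]
            assert comp["sex"] == ref["sex"]

    def test_unknowns_excluded(self):
        meta = _metadata(
            [["d1", "X", "unknown", "adult"], ["d2", "X", "female", "adult"]]
        )
        ref = {"age_class": {"adult": 1}, "sex": {"female": 1}}
        draws = conservative_match(meta, ref, n_draws=1, seed=0)
        assert draws == [["d2"]]


class TestDisjointPartition:
    def test_exact_partition_55(self):
        sets = disjoint_partition([f"i{k}" for k in range(55)], 11, seed=0)
        assert len(sets) == 5
        flat = [x for s in sets for x in s]
        assert len(flat) == len(set(flat)) == 55

    def test_floor_partition_239(self):
        sets = disjoint_partition([f"i{k}" for k in range(239)], 11, seed=0)
        assert len(sets) == 21  # floor(239/11); 8 leftover unused
        assert all(len(s) == 11 for s in sets)

    def test_insufficient(self):
        with pytest.raises(InsufficientSampleError):
            disjoint_partition(list("abcdefghij"), 11)

    def test_n_subsamples_override(self):
        sets = disjoint_partition([f"i{k}" for k in range(239)], 11, 0, n_subsamples=19)
        assert len(sets) == 19


class TestTTests:
    def test_identical_groups(self):
        t, df, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_large_shift_significant(self):
        t, df, p = two_sample_t([1, 2, 3], [11, 12, 13])
        assert p < 0.001

    def test_df_19_vs_5(self):
        t, df, p = two_sample_t(list(range(19)), list(range(5)))
        assert df == 22

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(0.3, size=6)
        t, df, p = two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_paired_identical(self):
        t, df, p = paired_t_over_loci([1.0, 2.0], [1.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_paired_df_23_loci(self):
        rng = np.random.default_rng(2)
        a = rng.random(23)
        b = a + rng.normal(0, 0.05, 23)
        t, df, p = paired_t_over_loci(a, b)
        assert df == 22
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)

    def test_paired_constant_difference_degenerate(self):
        t, df, p = paired_t_over_loci([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        assert np.isinf(t) and p == 0.0


class TestSexRatio:
    def test_even_split(self):
        chi2, p = sex_ratio_chisq(50, 50)
        assert chi2 == 0.0 and p == 1.0

    def test_60_40_worked_value(self):
        chi2, _ = sex_ratio_chisq(60, 40)
        assert chi2 == pytest.approx(4.0)

    def test_homogeneity_identical_counts(self):
        chi2, p = sex_ratio_chisq(30, 20, reference_counts=(30, 20))
        assert chi2 == pytest.approx(0.0)


def _small_scenario(seed):
    cfg = paper_like_config(seed)
    cfg.populations["A"].n_individuals = 120
    cfg.populations["B"].n_individuals = 33
    part = default_partition()
    alns, metas, msats = [], [], []
    for pop in ("A", "B"):
        aln, meta = simulate_population(cfg, pop, partition=part)
        ms = simulate_msat(cfg, pop, individual_ids=meta["id"].tolist())
        alns.append(aln)
        metas.append(meta)
        msats.append(ms)
    aln = PhasedAlignment(
        [s for a in alns for s in a.sequences],
        [i for a in alns for i in a.individual_ids],
        [h for a in alns for h in a.haplotype_index],
        [p for a in alns for p in a.populations],
        frame_offset=2,
    )
    ms = MsatDataset(
        [i for m in msats for i in m.individuals],
        msats[0].loci,
        np.concatenate([m.genotypes for m in msats]),
        [p for m in msats for p in m.populations],
    )
    return aln, ms, pd.concat(metas, ignore_index=True)


class TestComparePopulations:
    def test_report_structure_and_determinism(self):
        aln, ms, meta = _small_scenario(4)
        plan = SamplingPlan(seed=11)
        rep1 = compare_populations(aln, ms, meta, "A", "B", plan)
        rep2 = compare_populations(aln, ms, meta, "A", "B", plan)
        # schema: diversity panel columns present
        for col in ("population", "sampling", "n", "pi", "Hd", "theta_w", "theta_eta", "Eta"):
            assert col in rep1.seq_table.columns
        assert set(rep1.t_tests["marker"]) == {"mhc", "msat"}
        # full reproducibility under a fixed master seed
        pd.testing.assert_frame_equal(rep1.seq_table, rep2.seq_table)
        pd.testing.assert_frame_equal(rep1.t_tests, rep2.t_tests)
        assert rep1.seeds == rep2.seeds

    def test_conservative_rows_match_reference_size(self):
        aln, ms, meta = _small_scenario(5)
        rep = compare_populations(aln, ms, meta, "A", "B", SamplingPlan(seed=3))
        cons = rep.seq_table[rep.seq_table["sampling"].str.startswith("conservative")]
        assert cons["n"].nunique() == 1  # all conservative samples same size
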