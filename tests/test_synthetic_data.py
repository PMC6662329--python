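"""Generator guarantees: frame safety, determinism, calibration knobs."""

import json

import numpy as np
import pytest

from divcompare.codon_selection import STOP_CODONS, pbr_variable_site_tally
from divcompare.io_formats import read_genotype_csv, read_phased_fasta
from divcompare.seq_stats import nucleotide_diversity
from divcompare.synthetic_data import (
    FRAME_OFFSET,
    PopulationConfig,
    ScenarioConfig,
    default_partition,
    expected_pool_diversity,
    generate_haplotype_pool,
    generate_scenario,
    null_config,
    paper_like_config,
    simulate_msat,
    simulate_population,
)
from divcompare.tajima_test import classify_nonsynonymous_columns

from conftest import make_alignment


def _pool_alignment(haps):
    """One copy of each pool haplotype as a phased alignment (pad to even)."""
    seqs = list(haps) + ([haps[0]] if len(haps) % 2 else [])
    return make_alignment(seqs, frame_offset=FRAME_OFFSET)


class TestHaplotypePool:
    def test_no_stop_codons_anywhere(self):
        for seed in range(5):
            cfg = paper_like_config(seed)
            for pop in ("A", "B"):
                haps, _, _ = generate_haplotype_pool(cfg, pop)
                for h in haps:
                    codons = [
                        h[FRAME_OFFSET + 3 * k : FRAME_OFFSET + 3 * k + 3]
                        for k in range(56)
                    ]
                    assert not set(codons) & STOP_CODONS

    def test_pure_pbr_nonsyn_placement(self):
        cfg = ScenarioConfig(seed=3)
        cfg.populations["A"] = PopulationConfig(
            n_haplotypes=15, n_variable_sites=12, placement_weights=(1.0, 0.0, 0.0)
        )
        haps, _, cols = generate_haplotype_pool(cfg, "A")
        aln = _pool_alignment(haps)
        part = default_partition()
        in_pbr, total = pbr_variable_site_tally(aln, part)
        assert total > 0 and in_pbr == total  # every variable site is PBR
        nonsyn = classify_nonsynonymous_columns(aln)
        variable = set(cols)
        observed_variable = {
            c
            for c in range(aln.L)
            if len({s[c] for s in aln.sequences}) > 1
        }
        assert observed_variable <= variable
        assert observed_variable <= nonsyn  # and nonsynonymous

    def test_dirichlet_concentration_limit(self):
        cfg = ScenarioConfig(seed=1)
        cfg.populations["A"] = PopulationConfig(
            n_haplotypes=20, dirichlet_alpha=1e6
        )
        _, freqs, _ = generate_haplotype_pool(cfg, "A")
        assert np.sum(freqs**2) == pytest.approx(1 / 20, rel=0.01)

    def test_single_haplotype_monomorphic_downstream(self):
        cfg = ScenarioConfig(seed=2)
        cfg.populations["A"] = PopulationConfig(
            n_individuals=10, n_haplotypes=1, n_variable_sites=0
        )
        aln, _ = simulate_population(cfg, "A")
        pi, _ = nucleotide_diversity(aln)
        assert pi == 0.0

    def test_placement_weight_sweep_monotone_pbr_fraction(self):
        fractions = []
        for w_pbr in (0.1, 0.5, 0.9):
            cfg = ScenarioConfig(seed=6)
            cfg.populations["A"] = PopulationConfig(
                n_haplotypes=20,
                n_variable_sites=24,
                placement_weights=(w_pbr, 0.0, 1.0 - w_pbr),
            )
            haps, _, _ = generate_haplotype_pool(cfg, "A")
            in_pbr, total = pbr_variable_site_tally(
                _pool_alignment(haps), default_partition()
            )
            fractions.append(in_pbr / total)
        assert fractions == sorted(fractions)


class TestSimulatePopulation:
    def test_fixed_seed_reproducible(self):
        cfg = null_config(9)
        a1, m1 = simulate_population(cfg, "A")
        a2, m2 = simulate_population(cfg, "A")
        assert a1.sequences == a2.sequences
        assert m1.equals(m2)

    def test_composition_apportioned_exactly(self):
        cfg = null_config(3)  # 55 individuals, conservative proportions
        _, meta = simulate_population(cfg, "A")
        ages = meta["age_class"].value_counts().to_dict()
        sexes = meta["sex"].value_counts().to_dict()
        assert ages == {"adult": 38, "juvenile": 15, "calf": 2}
        assert sexes == {"male": 32, "female": 23}

    def test_individual_heterozygosity_tracks_pool(self):
        cfg = ScenarioConfig(seed=5)
        cfg.populations["A"] = PopulationConfig(
            n_individuals=1000, n_haplotypes=12, dirichlet_alpha=2.0
        )
        pool = generate_haplotype_pool(cfg, "A")
        aln, _ = simulate_population(cfg, "A", pool=pool)
        haps, freqs, _ = pool
        lut = {h: k for k, h in enumerate(haps)}
        het = np.mean(
            [
                lut[aln.sequences[2 * i]] != lut[aln.sequences[2 * i + 1]]
                for i in range(1000)
            ]
        )
        expected = 1 - np.sum(np.asarray(freqs) ** 2)
        assert het == pytest.approx(expected, abs=0.05)


class TestSimulateMsat:
    def test_no_missing_when_rate_zero(self):
        cfg = null_config(1)
        cfg.msat["A"].missing_rate = 0.0
        ds = simulate_msat(cfg, "A")
        assert ds.missing_mask().sum() == 0

    def test_inbreeding_knob_detected_by_hwe(self):
        from divcompare.msat_stats import hwe_test

        flagged = 0
        for seed in range(20):
            cfg = ScenarioConfig(seed=seed)
            cfg.populations["A"] = PopulationConfig(n_individuals=500)
            cfg.msat["A"].n_loci = 1
            cfg.msat["A"].inbreeding_f = 0.5
            cfg.msat["A"].missing_rate = 0.0
            ds = simulate_msat(cfg, "A")
            if hwe_test(ds, ds.loci[0]) < 0.05:
                flagged += 1
        assert flagged >= 18  # power > 0.95 at n=500, F=0.5

    def test_reproducible(self):
        cfg = null_config(4)
        d1 = simulate_msat(cfg, "B")
        d2 = simulate_msat(cfg, "B")
        assert np.array_equal(d1.genotypes, d2.genotypes)


class TestScenarioBundle:
    def test_manifest_round_trip(self, tmp_path):
        cfg = null_config(7)
        manifest = generate_scenario(cfg, tmp_path)
        aln = read_phased_fasta(tmp_path / "alignment.fasta", frame_offset=2)
        ds = read_genotype_csv(tmp_path / "genotypes.csv")
        dims = manifest["dimensions"]
        assert aln.n == dims["n_haplotype_copies"]
        assert aln.L == dims["L"]
        assert ds.n_individuals == dims["n_individuals"]
        assert ds.n_loci == dims["n_loci"]
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert on_disk["dimensions"] == dims

    def test_paper_like_pools_have_target_diversity_ratio(self):
        cfg = paper_like_config(0)
        part = default_partition()
        pi = {
            pop: expected_pool_diversity(*generate_haplotype_pool(cfg, pop, part)[:2])
            for pop in ("A", "B")
        }
        assert 1.1 < pi["A"] / pi["B"] < 1.5

    def test_pi_estimator_recovers_pool_diversity(self):
        """Across many scenarios, sample pi is unbiased for the pool's
        expected pairwise diversity (relative bias < 2%)."""
        rng = np.random.default_rng(0)
        ratios = []
        for k in range(300):
            cfg = ScenarioConfig(seed=int(rng.integers(2**31)))
            cfg.populations["A"] = PopulationConfig(
                n_individuals=30, n_haplotypes=15, n_variable_sites=20
            )
            pool = generate_haplotype_pool(cfg, "A")
            expected = expected_pool_diversity(pool[0], pool[1])
            if expected == 0:
                continue
            aln, _ = simulate_population(cfg, "A", pool=pool)
            pi, _ = nucleotide_diversity(aln)
            ratios.append(pi / expected)
        assert abs(np.mean(ratios) - 1.0) < 0.02
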