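"""Two-population synthetic fixtures with the structure the analysis assumes.

The generator emulates, without downloads, the statistical shape of the real
study system: a 172-bp in-frame MHC-like amplicon whose variable sites are
concentrated at nonsynonymous positions of the peptide-binding codons, two
populations with unequal haplotype richness and nucleotide diversity, and
multiallelic microsatellites near Hardy-Weinberg equilibrium with similar
diversity in both populations.

Haplotype pools are constructed directly (no coalescent machinery): K
distinct haplotypes derive from a shared stop-free base sequence by toggling
alternative bases at V variable sites, each haplotype carrying the
alternative at a site with probability q; pool frequencies are symmetric
Dirichlet(alpha). The expected pairwise diversity of a realized pool is
computable exactly, which parameter-recovery tests exploit.

A separate helper draws neutral infinite-sites alignments from a standard
coalescent (via msprime) for estimator-calibration work.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codon_selection import CODON_TO_AA, STOP_CODONS, _NUCS
from .errors import GenerationError
from .io_formats import (
    CodonPartition,
    MsatDataset,
    PhasedAlignment,
    write_codon_partition,
    write_genotype_csv,
    write_metadata_csv,
    write_phased_fasta,
)

AMPLICON_LENGTH = 172
FRAME_OFFSET = 2  # 2 leading bases, 56 complete codons, 2 trailing bases
TOTAL_CODONS = 56
#: 17 of the 56 codons flagged as peptide-binding (evenly spread default)
DEFAULT_PBR_CODONS = frozenset(range(2, 52, 3))  # 2, 5, ..., 50

#: conservative-sample demographics: 2 calves, 15 juveniles, 38 adults;
#: 32 males, 23 females (proportions of 55)
DEFAULT_AGE_PROPS = {"calf": 2 / 55, "juvenile": 15 / 55, "adult": 38 / 55}
DEFAULT_SEX_PROPS = {"male": 32 / 55, "female": 23 / 55}


@dataclass
class PopulationConfig:
    """Generator knobs for one population's MHC-like locus."""

    n_individuals: int = 55
    n_haplotypes: int = 20  # target pool richness K
    n_variable_sites: int = 30
    alt_allele_prob: float = 0.20  # per-site chance a haplotype is derived
    #: placement weights over (PBR-nonsynonymous, PBR-synonymous, non-PBR)
    placement_weights: tuple[float, float, float] = (0.70, 0.12, 0.18)
    dirichlet_alpha: float = 5.0


@dataclass
class MsatConfig:
    """Generator knobs for the microsatellite panel (shared shape per pop)."""

    n_loci: int = 23
    min_alleles: int = 3
    max_alleles: int = 10
    freq_dirichlet_alpha: float = 1.0
    missing_rate: float = 0.02
    inbreeding_f: float = 0.0  # heterozygote-deficit knob


@dataclass
class ScenarioConfig:
    """Full two-population scenario."""

    seed: int = 0
    populations: dict[str, PopulationConfig] = field(
        default_factory=lambda: {"A": PopulationConfig(), "B": PopulationConfig()}
    )
    msat: dict[str, MsatConfig] = field(
        default_factory=lambda: {"A": MsatConfig(), "B": MsatConfig()}
    )
    age_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_PROPS)
    )
    sex_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEX_PROPS)
    )
    shared_msat_frequencies: bool = True  # both pops draw from one freq set
    #: draw both populations from one haplotype pool (true null: the
    #: populations are identical and only sampling noise separates them)
    shared_haplotype_pool: bool = False

    def validate(self) -> None:
        for name, pc in self.populations.items():
            if pc.n_individuals < 2:
                raise GenerationError(f"population {name}: n_individuals < 2")
            if not 0.0 < pc.alt_allele_prob < 1.0:
                raise GenerationError(f"population {name}: alt_allele_prob not in (0,1)")
            w = pc.placement_weights
            if any(x < 0 for x in w) or sum(w) == 0:
                raise GenerationError(f"population {name}: bad placement weights")

    # -- (de)serialisation for the CLI ------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["populations"] = {
            k: PopulationConfig(**v) for k, v in raw.get("populations", {}).items()
        }
        raw["msat"] = {k: MsatConfig(**v) for k, v in raw.get("msat", {}).items()}
        return cls(**raw)


def paper_like_config(seed: int = 0) -> ScenarioConfig:
    """Richer MHC pool in population A (diversity ratio ~1.25-1.3), equal
    microsatellite settings — the study's qualitative contrast."""
    cfg = ScenarioConfig(seed=seed)
    cfg.populations = {
        "A": PopulationConfig(
            n_individuals=239,
            n_haplotypes=40,
            n_variable_sites=30,
            alt_allele_prob=0.28,
        ),
        "B": PopulationConfig(
            n_individuals=55,
            n_haplotypes=20,
            n_variable_sites=30,
            alt_allele_prob=0.20,
        ),
    }
    return cfg


def null_config(seed: int = 0) -> ScenarioConfig:
    """Identical settings in both populations (calibration scenario)."""
    cfg = ScenarioConfig(seed=seed)
    cfg.populations = {
        "A": PopulationConfig(n_individuals=55, n_haplotypes=25),
        "B": PopulationConfig(n_individuals=55, n_haplotypes=25),
    }
    cfg.shared_haplotype_pool = True
    return cfg


def child_seed(master: int, label: str) -> int:
    """Deterministic per-component seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# base sequence and site classification
# ---------------------------------------------------------------------------

def base_amplicon(seed: int) -> str:
    """A deterministic stop-free 172-bp base sequence in the default frame."""
    rng = np.random.default_rng(child_seed(seed, "base"))
    sense = sorted(CODON_TO_AA)
    codons = [sense[i] for i in rng.integers(0, len(sense), size=TOTAL_CODONS)]
    pad = "".join("ACGT"[i] for i in rng.integers(0, 4, size=4))
    return pad[:FRAME_OFFSET] + "".join(codons) + pad[FRAME_OFFSET:]


def default_partition() -> CodonPartition:
    return CodonPartition(DEFAULT_PBR_CODONS, TOTAL_CODONS)


def _site_catalogue(base: str, partition: CodonPartition):
    """Candidate substitution sites grouped by placement category.

    Each candidate is (alignment_column, alt_base); substitutions creating
    stop codons are rejected; categories: PBR-nonsynonymous, PBR-synonymous,
    non-PBR (any effect).
    """
    cats: dict[str, list[tuple[int, str]]] = {
        "pbr_nonsyn": [],
        "pbr_syn": [],
        "nonpbr": [],
    }
    for codon_idx in range(1, partition.total_codons + 1):
        start = FRAME_OFFSET + 3 * (codon_idx - 1)
        codon = base[start : start + 3]
        for k in range(3):
            for alt in _NUCS:
                if alt == codon[k]:
                    continue
                mutant = codon[:k] + alt + codon[k + 1 :]
                if mutant in STOP_CODONS:
                    continue
                col = start + k
                syn = CODON_TO_AA[mutant] == CODON_TO_AA[codon]
                if codon_idx in partition.pbr_codons:
                    cats["pbr_syn" if syn else "pbr_nonsyn"].append((col, alt))
                else:
                    cats["nonpbr"].append((col, alt))
    return cats


def generate_haplotype_pool(
    config: ScenarioConfig,
    population: str,
    partition: CodonPartition | None = None,
    max_attempts: int = 200,
):
    """Construct a population's haplotype pool.

    Returns ``(haplotypes, frequencies, site_columns)`` where haplotypes are
    distinct 172-bp stop-free strings and frequencies come from a symmetric
    Dirichlet. Variable-site columns are drawn by the placement weights;
    nonsynonymous placements are verified against the codon table.
    """
    config.validate()
    pc = config.populations[population]
    partition = partition or default_partition()
    base = base_amplicon(config.seed)
    rng = np.random.default_rng(child_seed(config.seed, f"pool:{population}"))
    cats = _site_catalogue(base, partition)
    names = ("pbr_nonsyn", "pbr_syn", "nonpbr")
    w = np.asarray(pc.placement_weights, dtype=float)
    w = w / w.sum()
    for _ in range(max_attempts):
        target = rng.multinomial(pc.n_variable_sites, w)
        chosen: list[tuple[int, str]] = []
        used_cols: set[int] = set()
        ok = True
        for name, count in zip(names, target):
            candidates = [c for c in cats[name] if c[0] not in used_cols]
            if len(candidates) < count:
                ok = False
                break
            idx = rng.choice(len(candidates), size=count, replace=False)
            for i in idx:
                col, alt = candidates[i]
                if col in used_cols:  # two alts at one column: keep first
                    continue
                chosen.append((col, alt))
                used_cols.add(col)
        if not ok:
            continue
        chosen = _drop_stop_combinations(base, chosen)
        K = pc.n_haplotypes
        patterns = rng.random((K, len(chosen))) < pc.alt_allele_prob
        haps = []
        for row in patterns:
            seq = list(base)
            for carry, (col, alt) in zip(row, chosen):
                if carry:
                    seq[col] = alt
            haps.append("".join(seq))
        if len(set(haps)) == K:
            freqs = rng.dirichlet(np.full(K, pc.dirichlet_alpha))
            cols = sorted(c for c, _ in chosen)
            return haps, freqs, cols
    raise GenerationError(
        f"could not build {pc.n_haplotypes} distinct stop-free haplotypes for "
        f"population {population} in {max_attempts} attempts"
    )


def _drop_stop_combinations(base: str, chosen: list[tuple[int, str]]):
    """Keep only sites whose joint ref/alt combinations within each codon
    are all sense codons (single substitutions are already stop-safe, but
    two substitutions in one codon can combine into a stop)."""
    import itertools

    by_codon: dict[int, list[tuple[int, str]]] = {}
    for col, alt in chosen:
        by_codon.setdefault((col - FRAME_OFFSET) // 3, []).append((col, alt))
    kept: list[tuple[int, str]] = []
    for codon_idx, sites in by_codon.items():
        start = FRAME_OFFSET + 3 * codon_idx
        ref = base[start : start + 3]
        safe: list[tuple[int, str]] = []
        for site in sorted(sites):
            trial = safe + [site]
            all_sense = True
            for mask in itertools.product([False, True], repeat=len(trial)):
                codon = list(ref)
                for on, (col, alt) in zip(mask, trial):
                    if on:
                        codon[col - start] = alt
                if "".join(codon) in STOP_CODONS:
                    all_sense = False
                    break
            if all_sense:
                safe = trial
        kept.extend(safe)
    return sorted(kept)


def expected_pool_diversity(haplotypes: list[str], frequencies) -> float:
    """Exact expected per-site pairwise diversity of a pool:
    sum_{i != j} p_i p_j d_ij / L (the population quantity the sample
    ``pi`` estimates after its n/(n-1) correction)."""
    mat = np.frombuffer(
        "".join(haplotypes).encode(), dtype="S1"
    ).reshape(len(haplotypes), -1)
    K, L = mat.shape
    p = np.asarray(frequencies, dtype=float)
    d = np.zeros((K, K))
    for i in range(K):
        d[i] = (mat[i] != mat).sum(axis=1)
    return float(p @ d @ p / L)


# ---------------------------------------------------------------------------
# sampling individuals
# ---------------------------------------------------------------------------

def simulate_population(
    config: ScenarioConfig,
    population: str,
    seed: int | None = None,
    pool=None,
    partition: CodonPartition | None = None,
):
    """Draw a diploid sample from a haplotype pool under random mating.

    Returns ``(PhasedAlignment, metadata DataFrame)``; metadata age class
    and sex are multinomial draws from the configured proportions.
    """
    pc = config.populations[population]
    if pool is None:
        pool = generate_haplotype_pool(config, population, partition)
    haps, freqs, _ = pool
    rng = np.random.default_rng(
        seed if seed is not None else child_seed(config.seed, f"sample:{population}")
    )
    n = pc.n_individuals
    draws = rng.choice(len(haps), size=2 * n, p=freqs)
    sequences, ids, hap_idx, pops = [], [], [], []
    for i in range(n):
        ind = f"{population}{i + 1:04d}"
        for h in (1, 2):
            sequences.append(haps[draws[2 * i + h - 1]])
            ids.append(ind)
            hap_idx.append(h)
            pops.append(population)
    alignment = PhasedAlignment(
        sequences, ids, hap_idx, pops, frame_offset=FRAME_OFFSET
    )
    age_draw = _apportion(config.age_proportions, n, rng)
    sex_draw = _apportion(config.sex_proportions, n, rng)
    metadata = pd.DataFrame(
        {
            "id": [f"{population}{i + 1:04d}" for i in range(n)],
            "population": population,
            "sex": sex_draw,
            "age_class": age_draw,
        }
    )
    return alignment, metadata


def _apportion(proportions: dict[str, float], n: int, rng) -> np.ndarray:
    """Assign categories to n individuals with exact largest-remainder
    counts (the design's composition is exact, not multinomial) in a
    random order."""
    cats = list(proportions)
    quotas = np.array([proportions[c] for c in cats], dtype=float)
    quotas = quotas / quotas.sum() * n
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts))[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(cats, counts)
    rng.shuffle(labels)
    return labels


def _msat_frequency_set(config: ScenarioConfig, label: str):
    """Per-locus allele labels and frequencies for one msat panel."""
    mc = config.msat[label]
    rng = np.random.default_rng(child_seed(config.seed, f"msat-freq:{label}"))
    loci = []
    for j in range(mc.n_loci):
        k = int(rng.integers(mc.min_alleles, mc.max_alleles + 1))
        freqs = rng.dirichlet(np.full(k, mc.freq_dirichlet_alpha))
        alleles = 100 + 2 * np.arange(k)  # fragment-length-like labels
        loci.append((alleles, freqs))
    return loci


def simulate_msat(
    config: ScenarioConfig,
    population: str,
    seed: int | None = None,
    individual_ids: list[str] | None = None,
) -> MsatDataset:
    """Genotypes under HWE with an optional heterozygote-deficit parameter F:
    P(hom k) = p_k^2 + F p_k (1 - p_k); missing entries at the configured
    rate."""
    mc = config.msat[population]
    freq_label = "A" if config.shared_msat_frequencies else population
    loci_freqs = _msat_frequency_set(config, freq_label)
    rng = np.random.default_rng(
        seed if seed is not None else child_seed(config.seed, f"msat:{population}")
    )
    n = (
        len(individual_ids)
        if individual_ids is not None
        else config.populations[population].n_individuals
    )
    ids = individual_ids or [f"{population}{i + 1:04d}" for i in range(n)]
    geno = np.empty((n, mc.n_loci, 2), dtype=np.int64)
    for j, (alleles, p) in enumerate(loci_freqs):
        a1 = rng.choice(len(p), size=n, p=p)
        if mc.inbreeding_f > 0:
            # with prob F the second allele copies the first (IBD)
            ibd = rng.random(n) < mc.inbreeding_f
            a2 = np.where(ibd, a1, rng.choice(len(p), size=n, p=p))
        else:
            a2 = rng.choice(len(p), size=n, p=p)
        geno[:, j, 0] = alleles[a1]
        geno[:, j, 1] = alleles[a2]
    missing = rng.random((n, mc.n_loci)) < mc.missing_rate
    geno[missing] = -1
    return MsatDataset(
        individuals=list(ids),
        loci=[f"L{j + 1:02d}" for j in range(mc.n_loci)],
        genotypes=geno,
        populations=[population] * n,
    )


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def generate_scenario(config: ScenarioConfig, out_dir: str | Path) -> dict:
    """Write a full fixture bundle (FASTA + CSVs + partition + manifest).

    The manifest records the true generating parameters, including each
    pool's exact expected pairwise diversity, for parameter-recovery tests.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partition = default_partition()
    alignments, metadatas, msats = [], [], []
    manifest: dict = {"seed": config.seed, "populations": {}}
    shared_pool = (
        generate_haplotype_pool(config, next(iter(config.populations)), partition)
        if config.shared_haplotype_pool
        else None
    )
    for pop in config.populations:
        pool = shared_pool or generate_haplotype_pool(config, pop, partition)
        aln, meta = simulate_population(config, pop, pool=pool, partition=partition)
        ms = simulate_msat(config, pop, individual_ids=meta["id"].tolist())
        alignments.append(aln)
        metadatas.append(meta)
        msats.append(ms)
        manifest["populations"][pop] = {
            "n_individuals": config.populations[pop].n_individuals,
            "n_haplotypes_pool": len(pool[0]),
            "n_variable_sites": len(pool[2]),
            "expected_pi": expected_pool_diversity(pool[0], pool[1]),
            "n_msat_loci": config.msat[pop].n_loci,
        }
    combined_aln = PhasedAlignment(
        sequences=[s for a in alignments for s in a.sequences],
        individual_ids=[i for a in alignments for i in a.individual_ids],
        haplotype_index=[h for a in alignments for h in a.haplotype_index],
        populations=[p for a in alignments for p in a.populations],
        frame_offset=FRAME_OFFSET,
    )
    combined_msat = MsatDataset(
        individuals=[i for m in msats for i in m.individuals],
        loci=msats[0].loci,
        genotypes=np.concatenate([m.genotypes for m in msats]),
        populations=[p for m in msats for p in m.populations],
    )
    combined_meta = pd.concat(metadatas, ignore_index=True)
    write_phased_fasta(combined_aln, out / "alignment.fasta")
    write_genotype_csv(combined_msat, out / "genotypes.csv")
    write_metadata_csv(combined_meta, out / "metadata.csv")
    write_codon_partition(partition, out / "pbr_partition.json")
    manifest["files"] = {
        "alignment": "alignment.fasta",
        "genotypes": "genotypes.csv",
        "metadata": "metadata.csv",
        "partition": "pbr_partition.json",
    }
    manifest["dimensions"] = {
        "n_haplotype_copies": combined_aln.n,
        "L": combined_aln.L,
        "n_individuals": combined_msat.n_individuals,
        "n_loci": combined_msat.n_loci,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# neutral coalescent fixtures (calibration only)
# ---------------------------------------------------------------------------

def neutral_coalescent_alignment(
    n: int, theta_locus: float, L: int, seed: int | None = None
):
    """Infinite-sites alignment of ``n`` haplotypes under a constant-size
    neutral coalescent with locus-wide theta = ``theta_locus``.

    Each mutation occupies its own column ('A' ancestral, 'T' derived) of a
    length-``L`` alignment; returns ``(PhasedAlignment, tree_sequence)`` so
    callers can cross-check against tskit's statistics. Requires msprime.
    """
    import msprime  # local import: calibration helper only

    if n % 2:
        raise ValueError("n must be even (haplotypes are paired per individual)")
    ts = msprime.sim_ancestry(
        samples=n // 2,
        ploidy=2,
        population_size=0.5,  # theta = 4 N mu = 2 mu per unit rate
        sequence_length=1.0,
        discrete_genome=False,
        random_seed=None if seed is None else seed + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=theta_locus / 2.0,
        discrete_genome=False,
        model=msprime.BinaryMutationModel(),
        random_seed=None if seed is None else seed + 1,
    )
    geno = ts.genotype_matrix()  # (n_sites, n_samples)
    S = geno.shape[0]
    if S > L:
        raise GenerationError(f"S={S} exceeds alignment length L={L}")
    cols = np.full((n, L), "A", dtype="U1")
    for j in range(S):
        cols[geno[j] > 0, j] = "T"
    sequences = ["".join(row) for row in cols]
    ids = [f"n{i // 2 + 1:04d}" for i in range(n)]
    haps = [1 + i % 2 for i in range(n)]
    aln = PhasedAlignment(sequences, ids, haps, ["sim"] * n, frame_offset=0)
    return aln, ts
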