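"""Microsatellite diversity, HWE/LD screening, locus filtering and F_ST.

Per-locus summaries follow the conventions of standard population-genetics
toolkits: observed heterozygosity Ho, expected heterozygosity He = 1 - sum
p^2 (uncorrected by default; the unbiased 2n/(2n-1) variant by flag),
effective allele number Ae = 1/sum p^2 and Shannon's index -sum p ln p.

Screening: chi-square goodness-of-fit HWE test per locus x population
(df = k(k-1)/2 for k alleles, Monte-Carlo option available), Bonferroni
across the loci x populations family, and a seeded permutation G-test for
genotypic linkage disequilibrium. F_ST defaults to the (Ht - mean Hs)/Ht
form averaged over loci; Weir-Cockerham theta is available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EmptyLocusError, InsufficientSampleError
from .io_formats import MsatDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    population: str
    n_typed: int
    Na: int
    Ae: float
    Ho: float
    He: float
    shannon: float
    hwe_p: float | None = None
    hwe_flag_after_bonferroni: bool = False

    def as_dict(self) -> dict:
        return {
            "locus": self.locus,
            "population": self.population,
            "n_typed": self.n_typed,
            "Na": self.Na,
            "Ae": self.Ae,
            "Ho": self.Ho,
            "He": self.He,
            "shannon": self.shannon,
            "hwe_p": self.hwe_p,
            "hwe_flag": self.hwe_flag_after_bonferroni,
        }


@dataclass(frozen=True)
class FstResult:
    per_locus: dict[str, float]
    mean: float
    estimator: str


def _typed_genotypes(dataset: MsatDataset, locus: str, population: str | None):
    j = dataset.locus_index(locus)
    if population is None:
        rows = np.arange(dataset.n_individuals)
    else:
        rows = np.array(
            [i for i, p in enumerate(dataset.populations) if p == population],
            dtype=int,
        )
    geno = dataset.genotypes[rows, j, :]
    typed = geno[~(geno < 1).any(axis=1)]
    return typed


def allele_frequencies(
    dataset: MsatDataset, locus: str, population: str | None = None
) -> dict[int, float]:
    """Allele frequency table over the 2 x n_typed allele copies."""
    typed = _typed_genotypes(dataset, locus, population)
    if typed.shape[0] == 0:
        raise EmptyLocusError(f"no typed individuals at {locus} in {population}")
    alleles, counts = np.unique(typed.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): float(c) / total for a, c in zip(alleles, counts)}


def locus_diversity(
    dataset: MsatDataset,
    locus: str,
    population: str | None = None,
    unbiased_he: bool = False,
) -> LocusDiversity:
    """Ho, He, Ae and Shannon index for one locus in one population."""
    typed = _typed_genotypes(dataset, locus, population)
    n_typed = typed.shape[0]
    if n_typed < 2:
        raise InsufficientSampleError(
            f"locus {locus}: fewer than 2 typed individuals"
        )
    freqs = allele_frequencies(dataset, locus, population)
    p = np.array(list(freqs.values()))
    sum_p2 = float(np.sum(p**2))
    he = 1.0 - sum_p2
    if unbiased_he:
        two_n = 2 * n_typed
        he *= two_n / (two_n - 1.0)
    ho = float(np.mean(typed[:, 0] != typed[:, 1]))
    ae = 1.0 / sum_p2
    shannon = float(-np.sum(p * np.log(p)))
    return LocusDiversity(
        locus=locus,
        population=population or "all",
        n_typed=n_typed,
        Na=len(freqs),
        Ae=ae,
        Ho=ho,
        He=he,
        shannon=shannon,
    )


def _hwe_chi2(typed: np.ndarray):
    """Chi-square statistic, df and genotype tables for a typed genotype set."""
    alleles = np.unique(typed.ravel())
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    n = typed.shape[0]
    obs = np.zeros((k, k))
    for a, b in typed:
        i, j = sorted((idx[a], idx[b]))
        obs[i, j] += 1
    counts = np.zeros(k)
    for a, b in typed:
        counts[idx[a]] += 1
        counts[idx[b]] += 1
    p = counts / counts.sum()
    chi2 = 0.0
    for i in range(k):
        for j in range(i, k):
            exp = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            if exp > 0:
                chi2 += (obs[i, j] - exp) ** 2 / exp
    df = k * (k - 1) // 2
    return chi2, df, k


def hwe_test(
    dataset: MsatDataset,
    locus: str,
    population: str | None = None,
    method: str = "chisq",
    n_mc: int = 2000,
    seed: int | None = None,
) -> float | None:
    """Hardy-Weinberg departure p-value for one locus x population.

    ``method='chisq'``: goodness-of-fit with df = k(k-1)/2.
    ``method='mc'``: seeded Monte-Carlo null built by re-pairing the observed
    allele copies at random, p = (1 + #{chi2_perm >= chi2_obs})/(1 + n_mc).
    Returns None for monomorphic loci (test not applicable).
    """
    typed = _typed_genotypes(dataset, locus, population)
    if typed.shape[0] < 2:
        raise InsufficientSampleError(f"locus {locus}: too few typed individuals")
    if typed.shape[0] < 5:
        logger.warning("HWE test at %s (%s): n<5, low power", locus, population)
    chi2, df, k = _hwe_chi2(typed)
    if k < 2:
        return None
    if method == "chisq":
        return float(stats.chi2.sf(chi2, df))
    if method == "mc":
        rng = np.random.default_rng(seed)
        pool = typed.ravel().copy()
        hits = 0
        for _ in range(n_mc):
            rng.shuffle(pool)
            perm = pool.reshape(-1, 2)
            c, _, _ = _hwe_chi2(perm)
            if c >= chi2 - 1e-12:
                hits += 1
        return (1.0 + hits) / (1.0 + n_mc)
    raise ValueError(f"unknown HWE method {method!r}")


def _g_statistic(table: np.ndarray) -> float:
    obs = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))


def ld_permutation_test(
    dataset: MsatDataset,
    locus_a: str,
    locus_b: str,
    population: str | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Permutation G-test for genotypic association between two loci.

    The observed G statistic on the genotype x genotype contingency table is
    compared with the null built by permuting one locus's genotypes across
    individuals; p honors the (1 + hits)/(1 + n_perm) lower bound.
    """
    ja, jb = dataset.locus_index(locus_a), dataset.locus_index(locus_b)
    if population is None:
        rows = np.arange(dataset.n_individuals)
    else:
        rows = np.array(
            [i for i, p in enumerate(dataset.populations) if p == population],
            dtype=int,
        )
    ga = dataset.genotypes[rows, ja, :]
    gb = dataset.genotypes[rows, jb, :]
    ok = ~((ga < 1).any(axis=1) | (gb < 1).any(axis=1))
    ga, gb = ga[ok], gb[ok]
    if ga.shape[0] < 2:
        raise InsufficientSampleError("too few jointly typed individuals")

    def codes(g):
        keys = [tuple(sorted(row)) for row in g]
        uniq = sorted(set(keys))
        lut = {u: i for i, u in enumerate(uniq)}
        return np.array([lut[k] for k in keys]), len(uniq)

    ca, ka = codes(ga)
    cb, kb = codes(gb)
    if ka < 2 or kb < 2:
        raise InsufficientSampleError("a locus is monomorphic in this population")

    def table(x, y):
        t = np.zeros((ka, kb))
        np.add.at(t, (x, y), 1)
        return t

    g_obs = _g_statistic(table(ca, cb))
    rng = np.random.default_rng(seed)
    hits = 0
    perm = cb.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _g_statistic(table(ca, perm)) >= g_obs - 1e-12:
            hits += 1
    return (1.0 + hits) / (1.0 + n_perm)


def fst_estimate(
    dataset: MsatDataset,
    grouping: dict[str, list[str]] | None = None,
    estimator: str = "ht-hs",
) -> FstResult:
    """Multi-locus F_ST across the groups given by ``grouping``
    (group label -> individual ids; defaults to the population labels).

    ``'ht-hs'``: per-locus (Ht - mean Hs)/Ht with Ht from pooled frequencies,
    averaged over informative loci. ``'weir-cockerham'``: Weir & Cockerham
    (1984) theta, variance components summed over alleles and loci.
    """
    if grouping is None:
        grouping = {}
        for ind, pop in zip(dataset.individuals, dataset.populations):
            grouping.setdefault(pop, []).append(ind)
    if len(grouping) < 2:
        raise InsufficientSampleError("F_ST requires >= 2 groups")
    subsets = {g: dataset.subset_individuals(ids) for g, ids in grouping.items()}
    per_locus: dict[str, float] = {}
    wc_num_total = wc_den_total = 0.0
    for locus in dataset.loci:
        freqs, sizes = [], []
        for sub in subsets.values():
            try:
                freqs.append(allele_frequencies(sub, locus))
                sizes.append(_typed_genotypes(sub, locus, None).shape[0])
            except EmptyLocusError:
                freqs.append(None)
        if any(f is None for f in freqs):
            logger.warning("locus %s skipped for F_ST: empty group", locus)
            continue
        alleles = sorted({a for f in freqs for a in f})
        P = np.array([[f.get(a, 0.0) for a in alleles] for f in freqs])
        if len(alleles) < 2:
            logger.warning("locus %s skipped for F_ST: monomorphic", locus)
            continue
        if estimator == "ht-hs":
            hs = 1.0 - np.sum(P**2, axis=1)
            pbar = P.mean(axis=0)
            ht = 1.0 - float(np.sum(pbar**2))
            per_locus[locus] = 0.0 if ht == 0 else float((ht - hs.mean()) / ht)
        elif estimator == "weir-cockerham":
            num, den = _wc_components(
                P, np.array(sizes, dtype=float), subsets, locus, alleles
            )
            per_locus[locus] = num / den if den > 0 else 0.0
            wc_num_total += num
            wc_den_total += den
        else:
            raise ValueError(f"unknown F_ST estimator {estimator!r}")
    if not per_locus:
        raise InsufficientSampleError("no informative loci for F_ST")
    if estimator == "weir-cockerham" and wc_den_total > 0:
        mean = wc_num_total / wc_den_total  # ratio-of-sums multilocus theta
    else:
        mean = float(np.mean(list(per_locus.values())))
    return FstResult(per_locus=per_locus, mean=mean, estimator=estimator)


def _wc_components(P: np.ndarray, n_i: np.ndarray, subsets, locus, alleles):
    """Weir-Cockerham (1984) variance components a (among) and a+b+c,
    summed over alleles of one locus. ``alleles`` gives the label for each
    column of ``P``."""
    r = P.shape[0]
    nbar = n_i.mean()
    nc = (n_i.sum() - np.sum(n_i**2) / n_i.sum()) / (r - 1)
    num = den = 0.0
    for a_idx, target in enumerate(alleles):
        p_i = P[:, a_idx]
        pbar = float(np.sum(n_i * p_i) / n_i.sum())
        s2 = float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        h_i = []
        for sub in subsets.values():
            typed = _typed_genotypes(sub, locus, None)
            het = float(
                np.mean((typed[:, 0] == target) ^ (typed[:, 1] == target))
            )
            h_i.append(het)
        hbar = float(np.sum(n_i * np.array(h_i)) / n_i.sum())
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        num += a
        den += a + b + c
    return num, den


def locus_qc_filter(
    dataset: MsatDataset,
    hwe_results: dict[tuple[str, str], float | None],
    alpha: float = 0.05,
) -> tuple[list[str], dict[str, str]]:
    """Retain loci passing Bonferroni-corrected HWE in every population.

    ``hwe_results`` maps (locus, population) -> p (None where not applicable).
    The Bonferroni family is loci x populations. Returns the retained locus
    list and a reasons map for the dropped loci.
    """
    family = [k for k, p in hwe_results.items() if p is not None]
    threshold = alpha / len(family) if family else 0.0
    dropped: dict[str, str] = {}
    for (locus, pop), p in hwe_results.items():
        if p is not None and p < threshold:
            reason = f"HWE departure in {pop} (p={p:.2e} < {threshold:.2e})"
            dropped[locus] = (
                dropped[locus] + "; " + reason if locus in dropped else reason
            )
    retained = [l for l in dataset.loci if l not in dropped]
    for locus, reason in dropped.items():
        logger.info("locus %s dropped: %s", locus, reason)
    return retained, dropped


def missing_and_deficit_warnings(
    dataset: MsatDataset,
    missing_rate_threshold: float = 0.2,
    deficit_threshold: float = 0.2,
) -> list[str]:
    """Frequency sanity screen: flag loci with high missingness or a large
    heterozygote deficit (He - Ho), the crude signature of null alleles."""
    warnings_out = []
    miss = dataset.missing_mask().mean(axis=0)
    for j, locus in enumerate(dataset.loci):
        if miss[j] > missing_rate_threshold:
            warnings_out.append(
                f"{locus}: missing rate {miss[j]:.2f} > {missing_rate_threshold}"
            )
        try:
            ld = locus_diversity(dataset, locus)
        except (InsufficientSampleError, EmptyLocusError):
            continue
        if ld.He - ld.Ho > deficit_threshold:
            warnings_out.append(
                f"{locus}: heterozygote deficit He-Ho={ld.He - ld.Ho:.2f}"
            )
    return warnings_out
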