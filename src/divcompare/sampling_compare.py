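"""Three-tier sampling design and inter-population comparisons.

The two study populations differ sharply in sample size, so diversity is
compared under three sampling tiers:

* **maximum** — everything genotyped/sequenced per marker system;
* **conservative** — equal-size draws from the larger population whose
  age-class and sex composition exactly matches the smaller population's
  sample (drift/demography-matched);
* **subsampling** — disjoint fixed-size subsamples (default 11 individuals)
  of each conservative set, giving replicate diversity values for t-tests.

Sequence measures (pi, Hd, theta_W, theta_Eta) are compared with pooled
two-sample t-tests across subsamples; microsatellite measures (Ho, He, Ae,
Shannon) with paired t-tests across loci. Sex ratios are screened with 1-df
chi-square tests against 50:50 or against reference counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CapacityError, InsufficientSampleError
from .io_formats import MsatDataset, PhasedAlignment
from .msat_stats import locus_diversity
from .seq_stats import DiversitySummary, diversity_summary

MEASURES_SEQ = ("pi", "Hd", "theta_w", "theta_eta")
MEASURES_MSAT = ("Ho", "He", "Ae", "shannon")


@dataclass(frozen=True)
class SamplingPlan:
    """Parameters of the three-tier sampling design."""

    approach: str = "all"  # 'maximum' | 'conservative' | 'subsampling' | 'all'
    reference_population: str | None = None
    n_conservative_draws: int = 3
    subsample_size: int = 11
    n_subsamples: int | None = None  # None -> floor(n / subsample_size)
    seed: int = 0


@dataclass
class ComparisonReport:
    """All per-tier tables plus the test outcomes, ready for TSV export."""

    seq_table: pd.DataFrame  # per population x sample diversity panel
    msat_table: pd.DataFrame  # per population x sampling mean Ho/He/Ae/1H
    msat_locus_table: pd.DataFrame  # per-locus detail
    t_tests: pd.DataFrame  # measure, tier, t, df, p
    chi_square: pd.DataFrame
    seeds: dict = field(default_factory=dict)


def composition_of(metadata: pd.DataFrame) -> dict:
    """Category histograms (marginal and joint age_class x sex) of a
    metadata table; unknowns are excluded from the joint table."""
    known = metadata[
        (metadata["age_class"] != "unknown") & (metadata["sex"] != "unknown")
    ]
    joint = (
        known.groupby(["age_class", "sex"], observed=True)["id"].count().to_dict()
    )
    return {
        "age_class": metadata["age_class"].value_counts().to_dict(),
        "sex": metadata["sex"].value_counts().to_dict(),
        "joint": joint,
    }


def conservative_match(
    metadata: pd.DataFrame,
    reference_composition: dict[str, dict[str, int]],
    n_draws: int,
    seed: int | None = None,
) -> list[list[str]]:
    """Draw ``n_draws`` disjoint individual sets matching a reference
    age-class x sex composition exactly.

    Matching is on the marginal histograms (so many calves, juveniles and
    adults; so many males and females), the way demography-matched designs
    are specified; the per-age sex split is chosen at random within the
    feasible range each draw. Individuals with unknown age class or sex are
    excluded from eligibility. Raises :class:`CapacityError` naming the
    deficient category when the source cannot supply ``n_draws`` disjoint
    sets.
    """
    rng = np.random.default_rng(seed)
    eligible = metadata[
        (metadata["age_class"] != "unknown") & (metadata["sex"] != "unknown")
    ]
    ref_age = {
        a: c
        for a, c in reference_composition["age_class"].items()
        if a != "unknown" and c > 0
    }
    ref_sex = {
        s: c
        for s, c in reference_composition["sex"].items()
        if s != "unknown" and c > 0
    }
    if sum(ref_age.values()) != sum(ref_sex.values()):
        raise CapacityError("age and sex marginals disagree in total")
    if set(ref_sex) - {"male", "female"}:
        raise CapacityError("sex marginals must use male/female")
    M = ref_sex.get("male", 0)
    draws: list[list[str]] = []
    used: set[str] = set()
    for d in range(n_draws):
        supply = {
            (age, sex): eligible[
                (eligible["age_class"] == age)
                & (eligible["sex"] == sex)
                & (~eligible["id"].isin(used))
            ]["id"].tolist()
            for age in ref_age
            for sex in ("male", "female")
        }
        ages = sorted(ref_age)
        lower, upper = {}, {}
        for age in ages:
            n_a = ref_age[age]
            if len(supply[(age, "male")]) + len(supply[(age, "female")]) < n_a:
                raise CapacityError(
                    f"draw {d + 1}: age class {age!r} needs {n_a}, only "
                    f"{len(supply[(age, 'male')]) + len(supply[(age, 'female')])} "
                    "unused individuals available"
                )
            lower[age] = max(0, n_a - len(supply[(age, "female")]))
            upper[age] = min(n_a, len(supply[(age, "male")]))
        if sum(lower.values()) > M or sum(upper.values()) < M:
            raise CapacityError(
                f"draw {d + 1}: sex marginal ({M} males) infeasible given "
                f"per-age supplies"
            )
        males = dict(lower)
        slack = M - sum(lower.values())
        while slack > 0:
            open_ages = [a for a in ages if males[a] < upper[a]]
            a = open_ages[rng.integers(len(open_ages))]
            males[a] += 1
            slack -= 1
        chosen: list[str] = []
        for age in ages:
            for sex, k in (("male", males[age]), ("female", ref_age[age] - males[age])):
                pool = supply[(age, sex)]
                picks = rng.choice(len(pool), size=k, replace=False) if k else []
                chosen.extend(pool[i] for i in picks)
        used.update(chosen)
        draws.append(sorted(chosen))
    return draws


def disjoint_partition(
    ids: list[str],
    subsample_size: int = 11,
    seed: int | None = None,
    n_subsamples: int | None = None,
) -> list[list[str]]:
    """Randomly partition ``ids`` into disjoint subsets of exact size.

    Yields ``floor(len(ids)/size)`` sets by default (capped by
    ``n_subsamples``); leftover individuals are unused.
    """
    if len(ids) < subsample_size:
        raise InsufficientSampleError(
            f"{len(ids)} individuals < subsample size {subsample_size}"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(ids)
    rng.shuffle(shuffled)
    k = len(ids) // subsample_size
    if n_subsamples is not None:
        if n_subsamples > k:
            raise InsufficientSampleError(
                f"requested {n_subsamples} subsamples, only {k} possible"
            )
        k = n_subsamples
    return [
        sorted(shuffled[i * subsample_size : (i + 1) * subsample_size])
        for i in range(k)
    ]


def two_sample_t(values_a, values_b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test; df = n_a + n_b - 2."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientSampleError("each group needs >= 2 values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float("inf"), df, 0.0
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), df, p


def paired_t_over_loci(values_a, values_b) -> tuple[float, int, float]:
    """Paired t-test across loci; df = n_loci - 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired t-test needs matched locus sets")
    if a.size < 2:
        raise InsufficientSampleError("paired t-test needs >= 2 loci")
    d = a - b
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, df, 1.0
        return float("inf"), df, 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), df, p


def sex_ratio_chisq(
    observed_m: int,
    observed_f: int,
    expected_ratio: float | None = 0.5,
    reference_counts: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """1-df chi-square against an expected male fraction, or a 2x2
    homogeneity test against reference (m, f) counts."""
    total = observed_m + observed_f
    if total == 0:
        raise InsufficientSampleError("no observed individuals")
    if reference_counts is not None:
        table = np.array([[observed_m, observed_f], list(reference_counts)])
        if (table.sum(axis=0) == 0).any():
            raise InsufficientSampleError("zero expected cell")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    exp_m = total * expected_ratio
    exp_f = total - exp_m
    if exp_m == 0 or exp_f == 0:
        raise InsufficientSampleError("zero expected cell")
    chi2 = (observed_m - exp_m) ** 2 / exp_m + (observed_f - exp_f) ** 2 / exp_f
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _seq_panel(alignment: PhasedAlignment, label: str, sampling: str) -> dict:
    summ = diversity_summary(alignment)
    row = {"population": label, "sampling": sampling}
    row.update(summ.as_dict())
    return row


def _msat_locus_rows(msat: MsatDataset, label: str, sampling: str) -> list[dict]:
    rows = []
    for locus in msat.loci:
        ld = locus_diversity(msat, locus)
        r = ld.as_dict()
        r["population"] = label
        r["sampling"] = sampling
        rows.append(r)
    return rows


def compare_populations(
    alignment: PhasedAlignment,
    msat: MsatDataset,
    metadata: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    plan: SamplingPlan,
) -> ComparisonReport:
    """Run the three sampling tiers for both marker systems and test the
    inter-population contrasts.

    ``pop_b`` is the smaller (reference) population whose conservative
    composition is matched in ``pop_a``. Returns per-tier tables, the
    t-test panel and the sex-ratio chi-square screen.
    """
    rng = np.random.default_rng(plan.seed)
    seeds = {
        "master": plan.seed,
        "conservative": int(rng.integers(2**31)),
        "subsample_a": int(rng.integers(2**31)),
        "subsample_b": int(rng.integers(2**31)),
    }
    meta_a = metadata[metadata["population"] == pop_a]
    meta_b = metadata[metadata["population"] == pop_b]
    aln_a, aln_b = alignment.subset_population(pop_a), alignment.subset_population(pop_b)
    msat_a, msat_b = msat.subset_population(pop_a), msat.subset_population(pop_b)

    seq_rows, msat_rows = [], []
    # --- maximum tier ----------------------------------------------------
    seq_rows.append(_seq_panel(aln_a, pop_a, "maximum"))
    seq_rows.append(_seq_panel(aln_b, pop_b, "maximum"))
    msat_rows += _msat_locus_rows(msat_a, pop_a, "maximum")
    msat_rows += _msat_locus_rows(msat_b, pop_b, "maximum")

    # --- conservative tier: both marker types available ------------------
    both_a = sorted(
        set(aln_a.individuals) & set(msat_a.individuals) & set(meta_a["id"])
    )
    both_b = sorted(
        set(aln_b.individuals) & set(msat_b.individuals) & set(meta_b["id"])
    )
    ref_comp = composition_of(meta_b[meta_b["id"].isin(both_b)])
    cons_sets_a = conservative_match(
        meta_a[meta_a["id"].isin(both_a)],
        ref_comp,
        plan.n_conservative_draws,
        seed=seeds["conservative"],
    )
    seq_rows.append(_seq_panel(aln_b.subset_individuals(both_b), pop_b, "conservative"))
    msat_rows += _msat_locus_rows(
        msat_b.subset_individuals(both_b), pop_b, "conservative"
    )
    for k, ids in enumerate(cons_sets_a, start=1):
        seq_rows.append(
            _seq_panel(aln_a.subset_individuals(ids), pop_a, f"conservative_{k}")
        )
        msat_rows += _msat_locus_rows(
            msat_a.subset_individuals(ids), pop_a, f"conservative_{k}"
        )

    # --- subsampling tier ------------------------------------------------
    pool_a = sorted({i for s in cons_sets_a for i in s})
    subs_a = disjoint_partition(
        pool_a, plan.subsample_size, seeds["subsample_a"], plan.n_subsamples
    )
    subs_b = disjoint_partition(
        both_b, plan.subsample_size, seeds["subsample_b"], plan.n_subsamples
    )
    sub_vals_a = {m: [] for m in MEASURES_SEQ}
    sub_vals_b = {m: [] for m in MEASURES_SEQ}
    for ids in subs_a:
        s = diversity_summary(aln_a.subset_individuals(ids)).as_dict()
        for m in MEASURES_SEQ:
            sub_vals_a[m].append(s[m])
    for ids in subs_b:
        s = diversity_summary(aln_b.subset_individuals(ids)).as_dict()
        for m in MEASURES_SEQ:
            sub_vals_b[m].append(s[m])
    for pop, subs, aln in ((pop_a, subs_a, aln_a), (pop_b, subs_b, aln_b)):
        for k, ids in enumerate(subs, start=1):
            seq_rows.append(
                _seq_panel(aln.subset_individuals(ids), pop, f"subsample_{k}")
            )

    # --- t-tests ---------------------------------------------------------
    t_rows = []
    for m in MEASURES_SEQ:
        t, df, p = two_sample_t(sub_vals_a[m], sub_vals_b[m])
        t_rows.append(
            {
                "marker": "mhc",
                "measure": m,
                "tier": "subsampling",
                "t": t,
                "df": df,
                "p": p,
            }
        )
    msat_locus_table = pd.DataFrame(msat_rows)
    cons_a_tables = [
        msat_locus_table[
            (msat_locus_table["population"] == pop_a)
            & (msat_locus_table["sampling"] == f"conservative_{k}")
        ].set_index("locus")
        for k in range(1, len(cons_sets_a) + 1)
    ]
    cons_b_table = msat_locus_table[
        (msat_locus_table["population"] == pop_b)
        & (msat_locus_table["sampling"] == "conservative")
    ].set_index("locus")
    for m in MEASURES_MSAT:
        per_locus_a = (
            pd.concat([t[m] for t in cons_a_tables], axis=1).mean(axis=1)
            if cons_a_tables
            else cons_b_table[m] * np.nan
        )
        aligned = pd.concat([per_locus_a, cons_b_table[m]], axis=1).dropna()
        t, df, p = paired_t_over_loci(aligned.iloc[:, 0], aligned.iloc[:, 1])
        t_rows.append(
            {
                "marker": "msat",
                "measure": m,
                "tier": "conservative",
                "t": t,
                "df": df,
                "p": p,
            }
        )

    # --- sex-ratio screen ------------------------------------------------
    chi_rows = []
    for pop, meta in ((pop_a, meta_a), (pop_b, meta_b)):
        m = int((meta["sex"] == "male").sum())
        f = int((meta["sex"] == "female").sum())
        if m + f:
            chi2, p = sex_ratio_chisq(m, f)
            chi_rows.append(
                {"population": pop, "test": "50:50", "chi2": chi2, "p": p}
            )

    # mean summary rows over microsatellite loci, per population x sampling
    msat_summary = (
        msat_locus_table.groupby(["population", "sampling"])[list(MEASURES_MSAT)]
        .agg(["mean", "sem"])
        .reset_index()
    )
    msat_summary.columns = [
        "_".join(c).rstrip("_") for c in msat_summary.columns.to_flat_index()
    ]

    return ComparisonReport(
        seq_table=pd.DataFrame(seq_rows),
        msat_table=msat_summary,
        msat_locus_table=msat_locus_table,
        t_tests=pd.DataFrame(t_rows),
        chi_square=pd.DataFrame(chi_rows),
        seeds=seeds,
    )
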