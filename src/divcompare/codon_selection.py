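"""Nei-Gojobori codon-based synonymous/nonsynonymous analysis.

The antigen-binding (PBR) codons of MHC genes are expected to show an excess
of amino-acid-changing substitutions under balancing selection, so the core
contrast here is dN vs dS computed separately for PBR, non-PBR and all
codons of the in-frame amplicon.

Method (Nei & Gojobori 1986, "unweighted pathway" variant):

* each sense codon contributes 3 sites, split into synonymous and
  nonsynonymous fractions by enumerating the 9 single-base mutants
  (changes creating stop codons are excluded from the fraction's
  denominator, so syn + nonsyn = 3 exactly per codon);
* pairwise differences between two codons are averaged over all orderings
  of the substitutions (pathways through stop codons excluded);
* per sequence pair, pN = Nd/N and pS = Sd/S with site totals averaged
  between the two sequences, Jukes-Cantor corrected
  ``d = -(3/4) ln(1 - 4p/3)``; dN and dS are means over all pairs.

Significance of dN - dS comes from a z-test whose standard error is the
spread of dN - dS over bootstrap resamples of the analyzed codon columns.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .errors import AmbiguityError, StopCodonError
from .io_formats import CodonPartition, PhasedAlignment

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
_NUCS = "ACGT"


@dataclass(frozen=True)
class SelectionTestResult:
    """dN/dS panel for one codon class, with the bootstrap z-test."""

    site_class: str  # 'pbr' | 'nonpbr' | 'all'
    n_codons: int
    dN: float
    dN_se: float
    dS: float
    dS_se: float
    ratio: float | None  # None when dS == 0 (flagged, not fabricated)
    z: float | None
    p: float | None  # two-sided unless one_sided was requested
    n_bootstrap: int
    seed: int | None

    @property
    def applicable(self) -> bool:
        return self.z is not None


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _NUCS for b in codon):
        raise AmbiguityError(f"codon {codon!r} contains ambiguous/illegal bases")
    if codon in STOP_CODONS:
        raise StopCodonError(f"{codon} is a stop codon")
    return codon


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Each position contributes one site, split by the fraction of its
    single-base changes (stop-codon changes excluded) that are synonymous.
    """
    codon = _check_codon(codon)
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        syn_changes = valid_changes = 0
        for base in _NUCS:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid_changes += 1
            if CODON_TO_AA[mutant] == aa:
                syn_changes += 1
        if valid_changes:
            syn += syn_changes / valid_changes
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pairwise_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts for a codon pair.

    Averages over all orderings of the differing positions; orderings that
    pass through a stop codon are dropped. Raises StopCodonError when no
    stop-free pathway exists (callers log and exclude the pair).
    """
    codon_a, codon_b = _check_codon(codon_a), _check_codon(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        raise StopCodonError(
            f"no stop-free substitution pathway between {codon_a} and {codon_b}"
        )
    return syn_total / n_paths, nonsyn_total / n_paths


def _codon_columns(alignment: PhasedAlignment, codon_indices) -> np.ndarray:
    """(n_seq, n_codons) array of 3-mer strings for the selected codons."""
    off = alignment.frame_offset
    out = np.empty((alignment.n, len(codon_indices)), dtype=object)
    for j, c in enumerate(codon_indices):
        start = off + 3 * (c - 1)
        for i, seq in enumerate(alignment.sequences):
            out[i, j] = seq[start : start + 3]
    return out


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction ``d = -(3/4) ln(1 - 4p/3)``."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 3/4: correction undefined")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


class _PairContributions:
    """Per-pair, per-codon Nei-Gojobori tallies for one codon-column set.

    ``syn_sites``/``nonsyn_sites``/``syn_diffs``/``nonsyn_diffs`` have shape
    (n_pairs, n_codons); ``weights`` holds the number of sequence pairs each
    distinct-haplotype pair represents. Codons with ambiguous bases in a pair
    contribute zeros to that pair (pairwise deletion at codon granularity);
    pairs with a stop-locked pathway are dropped with a log entry.
    """

    def __init__(self, codon_cols: np.ndarray):
        rows = ["\x00".join(r) for r in codon_cols]
        uniq, inverse, counts = np.unique(
            rows, return_inverse=True, return_counts=True
        )
        reps = [codon_cols[np.flatnonzero(inverse == k)[0]] for k in range(len(uniq))]
        K = len(reps)
        n_codons = codon_cols.shape[1]
        pair_rows = []
        weights = []
        for i in range(K):
            if counts[i] >= 2:
                pair_rows.append((i, i))
                weights.append(counts[i] * (counts[i] - 1) / 2.0)
            for j in range(i + 1, K):
                pair_rows.append((i, j))
                weights.append(float(counts[i] * counts[j]))
        P = len(pair_rows)
        self.syn_sites = np.zeros((P, n_codons))
        self.nonsyn_sites = np.zeros((P, n_codons))
        self.syn_diffs = np.zeros((P, n_codons))
        self.nonsyn_diffs = np.zeros((P, n_codons))
        keep = np.ones(P, dtype=bool)
        for p_idx, (i, j) in enumerate(pair_rows):
            ca_row, cb_row = reps[i], reps[j]
            any_codon = False
            try:
                for c in range(n_codons):
                    ca, cb = ca_row[c], cb_row[c]
                    if any(ch not in _NUCS for ch in ca + cb):
                        continue
                    sa = codon_site_counts(ca)
                    sb = codon_site_counts(cb)
                    sd, nd = pairwise_codon_differences(ca, cb)
                    self.syn_sites[p_idx, c] = (sa[0] + sb[0]) / 2.0
                    self.nonsyn_sites[p_idx, c] = (sa[1] + sb[1]) / 2.0
                    self.syn_diffs[p_idx, c] = sd
                    self.nonsyn_diffs[p_idx, c] = nd
                    any_codon = True
            except StopCodonError as exc:
                logger.warning("pair excluded from dN/dS: %s", exc)
                keep[p_idx] = False
                continue
            if not any_codon:
                keep[p_idx] = False
        self.syn_sites = self.syn_sites[keep]
        self.nonsyn_sites = self.nonsyn_sites[keep]
        self.syn_diffs = self.syn_diffs[keep]
        self.nonsyn_diffs = self.nonsyn_diffs[keep]
        self.weights = np.asarray(weights)[keep]
        if self.weights.size == 0 or self.weights.sum() == 0:
            raise AmbiguityError("no comparable sequence pairs")

    def mean_distances(self, cols: np.ndarray | None = None) -> tuple[float, float]:
        """Weighted mean (dN, dS) over pairs, optionally on resampled codons."""
        sl = slice(None) if cols is None else cols
        ss = self.syn_sites[:, sl].sum(axis=1)
        ns = self.nonsyn_sites[:, sl].sum(axis=1)
        sd = self.syn_diffs[:, sl].sum(axis=1)
        nd = self.nonsyn_diffs[:, sl].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pN = np.where(ns > 0, nd / np.maximum(ns, 1e-300), 0.0)
            pS = np.where(ss > 0, sd / np.maximum(ss, 1e-300), 0.0)
        ok = (pN < 0.75) & (pS < 0.75)
        if not ok.all():
            logger.debug(
                "%d pair(s) excluded: proportion >= 3/4, JC correction undefined",
                int((~ok).sum()),
            )
        w = self.weights[ok]
        if w.sum() == 0:
            raise AmbiguityError("no comparable sequence pairs after JC filter")
        dn = -0.75 * np.log1p(-4.0 * pN[ok] / 3.0)
        ds = -0.75 * np.log1p(-4.0 * pS[ok] / 3.0)
        return float(np.average(dn, weights=w)), float(np.average(ds, weights=w))


def _mean_distances(codon_cols: np.ndarray) -> tuple[float, float]:
    return _PairContributions(codon_cols).mean_distances()


def nei_gojobori_distances(
    alignment: PhasedAlignment,
    partition: CodonPartition,
    site_class: str = "all",
) -> tuple[float, float]:
    """Mean pairwise (dN, dS) over the codon subset selected by site_class."""
    codon_cols = _codon_columns(alignment, partition.codons_for(site_class))
    return _mean_distances(codon_cols)


def selection_z_test(
    alignment: PhasedAlignment,
    partition: CodonPartition,
    site_class: str = "all",
    n_bootstrap: int = 1000,
    seed: int | None = None,
    one_sided: bool = False,
) -> SelectionTestResult:
    """Codon-based test of positive selection (dN vs dS z-test).

    The standard error of dN - dS comes from ``n_bootstrap`` resamples of
    the analyzed codon columns (with replacement); z = (dN - dS)/se with a
    normal reference. The one-sided variant tests dN > dS specifically.
    """
    codon_indices = partition.codons_for(site_class)
    codon_cols = _codon_columns(alignment, codon_indices)
    contrib = _PairContributions(codon_cols)
    dN, dS = contrib.mean_distances()
    n_codons = len(codon_indices)
    monomorphic = all(
        len(set(codon_cols[:, j])) == 1 for j in range(codon_cols.shape[1])
    )
    if monomorphic:
        return SelectionTestResult(
            site_class, n_codons, dN, 0.0, dS, 0.0, None, None, None, 0, seed
        )
    rng = np.random.default_rng(seed)
    reps_dn = np.empty(n_bootstrap)
    reps_ds = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        cols = rng.integers(0, codon_cols.shape[1], size=codon_cols.shape[1])
        try:
            reps_dn[b], reps_ds[b] = contrib.mean_distances(cols)
        except AmbiguityError:
            reps_dn[b], reps_ds[b] = np.nan, np.nan
    diff = reps_dn - reps_ds
    diff = diff[np.isfinite(diff)]
    se = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    dn_se = float(np.nanstd(reps_dn, ddof=1))
    ds_se = float(np.nanstd(reps_ds, ddof=1))
    if se == 0.0:
        z = p = None
    else:
        z = (dN - dS) / se
        p = (
            float(stats.norm.sf(z))
            if one_sided
            else float(2.0 * stats.norm.sf(abs(z)))
        )
    ratio = dN / dS if dS > 0 else None
    return SelectionTestResult(
        site_class, n_codons, dN, dn_se, dS, ds_se, ratio, z, p, n_bootstrap, seed
    )


def pbr_variable_site_tally(
    alignment: PhasedAlignment,
    partition: CodonPartition,
    max_missing_frac: float = 0.0,
) -> tuple[int, int]:
    """Count variable nucleotide sites inside vs across all analyzed codons.

    Returns ``(variable_sites_in_pbr, variable_sites_total)`` over usable
    columns belonging to complete codons of the reading frame.
    """
    from .seq_stats import usable_columns  # local import avoids cycle

    cols = usable_columns(alignment, max_missing_frac)
    mat = alignment.as_matrix()
    off = alignment.frame_offset
    in_pbr = total = 0
    for col in cols:
        if col < off:
            continue
        codon_idx = (col - off) // 3 + 1
        if codon_idx > partition.total_codons:
            continue
        bases = {b for b in mat[:, col] if b in (b"A", b"C", b"G", b"T")}
        if len(bases) >= 2:
            total += 1
            if codon_idx in partition.pbr_codons:
                in_pbr += 1
    return in_pbr, total
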