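"""Tajima's D on all sites and on nonsynonymous sites only.

D contrasts the pairwise-difference estimator of the population mutation
parameter with the segregating-sites estimator:

    D = (k_bar - S/a1) / sqrt(e1*S + e2*S*(S-1))

Negative values indicate an excess of rare variants (purifying/directional
selection or expansion); positive values an excess of intermediate-frequency
variants (balancing selection or structure). For an MHC amplicon the test is
additionally run on the nonsynonymous columns only, where selection acts.

Significance uses Tajima (1989)'s beta-distribution approximation: D is
assumed to follow a generalised beta on [D_min, D_max] with mean 0 and
variance 1, where the limits are the theoretical extremes at large S.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .codon_selection import CODON_TO_AA, STOP_CODONS, _NUCS
from .errors import InsufficientSampleError
from .io_formats import PhasedAlignment
from .seq_stats import usable_columns

SIGNIFICANCE_CLASSES = ("p > 0.10", "0.10 > p > 0.05", "p < 0.05", "p < 0.01")


@dataclass(frozen=True)
class TajimaResult:
    site_filter: str  # 'all' | 'nonsynonymous'
    n: int
    S_used: int
    D: float | None
    p: float | None
    significance_class: str  # one of SIGNIFICANCE_CLASSES or 'not-applicable'

    @property
    def applicable(self) -> bool:
        return self.D is not None


def tajima_constants(n: int) -> tuple[float, float, float, float, float, float, float, float]:
    """The (a1, a2, b1, b2, c1, c2, e1, e2) constants of Tajima (1989)."""
    if n < 2:
        raise InsufficientSampleError("Tajima constants require n >= 2")
    if n < 4:
        warnings.warn(f"Tajima's D is degenerate for n={n}", stacklevel=2)
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def classify_nonsynonymous_columns(
    alignment: PhasedAlignment, max_missing_frac: float = 0.0
) -> set[int]:
    """Variable usable columns whose base exchanges change the amino acid.

    A variable column is nonsynonymous if, within the observed codon
    context(s), exchanging its observed bases alters the encoded residue.
    For codons with several variable positions the observed codon pairs are
    resolved by minimal stop-free pathway enumeration; the column counts as
    nonsynonymous only if every minimal pathway changes the amino acid at
    the step involving this column.
    """
    cols = set(usable_columns(alignment, max_missing_frac).tolist())
    mat = alignment.as_matrix()
    off = alignment.frame_offset
    n_codons = (alignment.L - off) // 3
    nonsyn: set[int] = set()
    for codon_idx in range(n_codons):
        start = off + 3 * codon_idx
        positions = [start, start + 1, start + 2]
        if not all(p in cols for p in positions):
            continue
        observed = {
            seq[start : start + 3]
            for seq in alignment.sequences
            if all(ch in _NUCS for ch in seq[start : start + 3])
            and seq[start : start + 3] not in STOP_CODONS
        }
        if len(observed) < 2:
            continue
        for ca, cb in itertools.combinations(sorted(observed), 2):
            diff = [k for k in range(3) if ca[k] != cb[k]]
            if len(diff) == 1:
                k = diff[0]
                if CODON_TO_AA.get(ca) != CODON_TO_AA.get(cb):
                    nonsyn.add(start + k)
            else:
                flagged = _pathway_nonsyn_offsets(ca, cb, diff)
                nonsyn.update(start + k for k in flagged)
    return nonsyn


def _pathway_nonsyn_offsets(ca: str, cb: str, diff: list[int]) -> set[int]:
    """Codon-position offsets whose step changes the residue in ALL minimal
    stop-free pathways between the two observed codons."""
    always: dict[int, bool] = {k: True for k in diff}
    any_path = False
    for order in itertools.permutations(diff):
        current = ca
        steps: dict[int, bool] = {}
        ok = True
        for k in order:
            nxt = current[:k] + cb[k] + current[k + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps[k] = CODON_TO_AA[current] != CODON_TO_AA[nxt]
            current = nxt
        if not ok:
            continue
        any_path = True
        for k, changed in steps.items():
            always[k] = always[k] and changed
    if not any_path:
        return set()
    return {k for k, v in always.items() if v}


def _beta_p_value(D: float, n: int) -> float:
    """Two-sided p for D under Tajima (1989)'s beta approximation."""
    a1, a2, b1, b2, c1, c2, e1, e2 = tajima_constants(n)
    if e2 <= 0:
        return float("nan")
    d_min = (2.0 / n - 1.0 / a1) / np.sqrt(e2)
    d_max = ((n + 1.0) / (2.0 * n) - 1.0 / a1) / np.sqrt(e2)
    span = d_max - d_min
    # moment-match a Beta on [d_min, d_max] to mean 0, variance 1
    m = -d_min / span
    v = 1.0 / span**2
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:
        return float("nan")
    alpha, beta = m * common, (1.0 - m) * common
    x = np.clip((D - d_min) / span, 0.0, 1.0)
    cdf = stats.beta.cdf(x, alpha, beta)
    return float(2.0 * min(cdf, 1.0 - cdf))


def _classify(p: float) -> str:
    if not np.isfinite(p):
        return "not-applicable"
    if p < 0.01:
        return "p < 0.01"
    if p < 0.05:
        return "p < 0.05"
    if p < 0.10:
        return "0.10 > p > 0.05"
    return "p > 0.10"


def tajima_D(
    alignment: PhasedAlignment,
    site_filter: str = "all",
    max_missing_frac: float = 0.0,
) -> TajimaResult:
    """Tajima's D over all usable columns or the nonsynonymous subset.

    ``k_bar`` is the mean raw pairwise difference count (not per site) over
    the filtered columns, matching Tajima's original formulation.
    """
    n = alignment.n
    if n < 2:
        raise InsufficientSampleError("Tajima's D requires n >= 2")
    cols = usable_columns(alignment, max_missing_frac)
    if site_filter == "nonsynonymous":
        keep = classify_nonsynonymous_columns(alignment, max_missing_frac)
        cols = np.array(sorted(set(cols.tolist()) & keep), dtype=int)
    elif site_filter != "all":
        raise ValueError(f"unknown site_filter {site_filter!r}")
    if cols.size == 0:
        return TajimaResult(site_filter, n, 0, None, None, "not-applicable")
    mat = alignment.as_matrix()[:, cols]
    variable = np.zeros(mat.shape[1], dtype=int)
    for base in (b"A", b"C", b"G", b"T"):
        variable += (mat == base).any(axis=0)
    S = int((variable >= 2).sum())
    if S == 0:
        return TajimaResult(site_filter, n, 0, None, None, "not-applicable")
    uniq, counts = np.unique(mat, axis=0, return_counts=True)
    K = uniq.shape[0]
    diff = np.zeros((K, K))
    for i in range(K):
        diff[i] = (uniq[i] != uniq).sum(axis=1)
    w = counts.astype(float)
    k_bar = 0.5 * (w @ diff @ w) / (n * (n - 1) / 2.0)
    a1, a2, b1, b2, c1, c2, e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return TajimaResult(site_filter, n, S, None, None, "not-applicable")
    D = float((k_bar - S / a1) / np.sqrt(var))
    p = _beta_p_value(D, n)
    return TajimaResult(site_filter, n, S, D, p, _classify(p))
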