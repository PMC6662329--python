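"""Sequence-level diversity estimators and their sampling variances.

Implements the classical single-locus summaries for a sample of ``n``
haplotype copies over ``L`` usable alignment columns:

* nucleotide diversity ``pi`` — expected per-site difference between two
  randomly drawn haplotypes, with the ``n/(n-1)`` sample correction,
* haplotype (gene) diversity ``Hd = n/(n-1) * (1 - sum x_k^2)``,
* Watterson's estimator ``theta_W = S / (a1 * L)`` from the count of
  segregating sites ``S``,
* ``theta_Eta = Eta / (a1 * L)`` from the minimum mutation count ``Eta``
  (a site with ``b`` distinct bases contributes ``b - 1`` mutations),

together with their sampling standard deviations (Nei 1987 for pi and Hd,
the Tajima 1993 moment estimator for theta_W).

Missing data policy: complete deletion — any column containing a gap or an
``N`` (beyond ``max_missing_frac``) is excluded from every statistic, so S,
Eta, pi and the thetas all share the same usable-site count ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientSampleError
from .io_formats import PhasedAlignment

_BASES = np.array([b"A", b"C", b"G", b"T"])


@dataclass(frozen=True)
class DiversitySummary:
    """One sample's diversity panel (the columns of a per-sample report row)."""

    n: int
    L: int
    S: int
    Eta: int
    pi: float
    pi_sd: float
    Hd: float
    Hd_sd: float
    theta_w: float
    theta_w_sd: float
    theta_eta: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "L": self.L,
            "S": self.S,
            "Eta": self.Eta,
            "pi": self.pi,
            "pi_sd": self.pi_sd,
            "Hd": self.Hd,
            "Hd_sd": self.Hd_sd,
            "theta_w": self.theta_w,
            "theta_w_sd": self.theta_w_sd,
            "theta_eta": self.theta_eta,
        }


def harmonic_a1(n: int) -> float:
    """``a1 = sum_{i=1}^{n-1} 1/i`` (Watterson's normaliser)."""
    return float(np.sum(1.0 / np.arange(1, n)))


def usable_columns(alignment: PhasedAlignment, max_missing_frac: float = 0.0) -> np.ndarray:
    """Indices of columns retained under complete deletion.

    A column is dropped if it contains any gap, or if its fraction of ``N``
    exceeds ``max_missing_frac`` (default 0: any N drops the column).
    """
    mat = alignment.as_matrix()
    has_gap = (mat == b"-").any(axis=0)
    n_frac = (mat == b"N").mean(axis=0)
    keep = ~has_gap & (n_frac <= max_missing_frac)
    return np.flatnonzero(keep)


def _usable_matrix(alignment: PhasedAlignment, max_missing_frac: float):
    cols = usable_columns(alignment, max_missing_frac)
    if cols.size == 0:
        raise DegenerateInputError("no usable columns after complete deletion")
    return alignment.as_matrix()[:, cols], cols


def segregating_sites_and_eta(
    alignment: PhasedAlignment, max_missing_frac: float = 0.0
) -> tuple[int, int, int]:
    """Return ``(S, Eta, L_usable)`` over the usable columns.

    ``S`` counts columns with >= 2 distinct bases; ``Eta`` adds one mutation
    per extra base at multi-allelic columns, so ``Eta >= S``.
    """
    mat, cols = _usable_matrix(alignment, max_missing_frac)
    distinct = np.zeros(mat.shape[1], dtype=int)
    for base in _BASES:
        distinct += (mat == base).any(axis=0)
    # N entries at tolerated columns are ignored in the base tally
    distinct = np.maximum(distinct, 1)
    S = int((distinct >= 2).sum())
    eta = int((distinct - 1).sum())
    return S, eta, int(cols.size)


def _pairwise_diff_stats(mat: np.ndarray) -> tuple[float, float]:
    """Mean raw pairwise difference count over all C(n,2) pairs, and L."""
    n, L = mat.shape
    # collapse to distinct rows for O(K^2 L) instead of O(n^2 L)
    uniq, counts = np.unique(mat, axis=0, return_counts=True)
    K = uniq.shape[0]
    if K == 1:
        return 0.0, float(L)
    diff = np.zeros((K, K))
    for i in range(K):
        diff[i] = (uniq[i] != uniq).sum(axis=1)
    w = counts.astype(float)
    total = 0.5 * (w @ diff @ w)  # sum over unordered cross-variant pairs
    n_pairs = n * (n - 1) / 2
    return float(total / n_pairs), float(L)


def nucleotide_diversity(
    alignment: PhasedAlignment, max_missing_frac: float = 0.0
) -> tuple[float, float]:
    """Per-site nucleotide diversity ``pi`` and its sampling SD.

    ``pi`` is the mean per-site difference over all unordered sequence pairs,
    equivalently the haplotype-frequency form with the ``n/(n-1)`` correction.
    The variance is Nei (1987)'s sampling variance

        V(pi) = (n+1) pi / (3 (n-1) L) + 2 (n^2 + n + 3) pi^2 / (9 n (n-1)).
    """
    n = alignment.n
    if n < 2:
        raise InsufficientSampleError("pi requires at least 2 sequences")
    mat, _ = _usable_matrix(alignment, max_missing_frac)
    k_bar, L = _pairwise_diff_stats(mat)
    pi = k_bar / L
    var = (n + 1) * pi / (3.0 * (n - 1) * L) + (
        2.0 * (n * n + n + 3) * pi * pi / (9.0 * n * (n - 1))
    )
    return pi, float(np.sqrt(max(var, 0.0)))


def haplotype_frequencies(alignment: PhasedAlignment) -> np.ndarray:
    """Sample frequencies of the distinct full-length sequence variants."""
    _, counts = np.unique(alignment.as_matrix(), axis=0, return_counts=True)
    return counts / counts.sum()


def haplotype_diversity(
    alignment: PhasedAlignment, sd_method: str = "nei_8.12"
) -> tuple[float, float]:
    """Haplotype diversity ``Hd`` and its SD.

    ``Hd = n/(n-1) (1 - sum x_k^2)`` over distinct sequence variants.
    ``sd_method='nei_8.12'`` (default) uses Nei (1987)'s single-locus
    sampling variance; ``'replication'`` uses the large-sample form
    ``(4/n) [sum x^3 - (sum x^2)^2]``.
    """
    n = alignment.n
    if n < 2:
        raise InsufficientSampleError("Hd requires at least 2 sequences")
    x = haplotype_frequencies(alignment)
    sum2 = float(np.sum(x**2))
    sum3 = float(np.sum(x**3))
    hd = n / (n - 1.0) * (1.0 - sum2)
    if sd_method == "nei_8.12":
        var = (
            2.0
            / (n * (n - 1.0))
            * (2.0 * (n - 2.0) * (sum3 - sum2**2) + sum2 - sum2**2)
        )
    elif sd_method == "replication":
        var = 4.0 / n * (sum3 - sum2**2)
    else:
        raise ValueError(f"unknown sd_method {sd_method!r}")
    return float(hd), float(np.sqrt(max(var, 0.0)))


def theta_estimators(S: int, Eta: int, n: int, L: int) -> tuple[float, float, float]:
    """Per-site ``(theta_W, theta_W_sd, theta_Eta)`` from S, Eta, n, L.

    The theta_W variance uses the moment estimator from
    ``Var(S) = a1 theta + a2 theta^2`` with the unbiased
    ``theta^2_hat = (S^2 - S) / (a1^2 + a2)``.
    """
    if n < 2:
        raise InsufficientSampleError("theta requires at least 2 sequences")
    if L < 1:
        raise DegenerateInputError("theta requires at least 1 usable site")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    theta_w = S / (a1 * L)
    theta_eta = Eta / (a1 * L)
    theta2 = (S * S - S) / (a1 * a1 + a2)
    var_theta_gene = (a1 * (S / a1) + a2 * theta2) / (a1 * a1)
    theta_w_sd = float(np.sqrt(max(var_theta_gene, 0.0)) / L)
    return float(theta_w), theta_w_sd, float(theta_eta)


def diversity_summary(
    alignment: PhasedAlignment,
    max_missing_frac: float = 0.0,
    hd_sd_method: str = "nei_8.12",
) -> DiversitySummary:
    """Full diversity panel for one sample (n, L, S, Eta, pi, Hd, thetas)."""
    S, eta, L = segregating_sites_and_eta(alignment, max_missing_frac)
    pi, pi_sd = nucleotide_diversity(alignment, max_missing_frac)
    hd, hd_sd = haplotype_diversity(alignment, sd_method=hd_sd_method)
    theta_w, theta_w_sd, theta_eta = theta_estimators(S, eta, alignment.n, L)
    return DiversitySummary(
        n=alignment.n,
        L=L,
        S=S,
        Eta=eta,
        pi=pi,
        pi_sd=pi_sd,
        Hd=hd,
        Hd_sd=hd_sd,
        theta_w=theta_w,
        theta_w_sd=theta_w_sd,
        theta_eta=theta_eta,
    )


def variant_count(alignment: PhasedAlignment) -> int:
    """Number of distinct full-length sequence variants in the sample."""
    return int(np.unique(alignment.as_matrix(), axis=0).shape[0])
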