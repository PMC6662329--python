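"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from divcompare.io_formats import MsatDataset, PhasedAlignment


def make_alignment(seqs, frame_offset=0, population="pop"):
    """Pair consecutive sequences into individuals (len(seqs) must be even)."""
    assert len(seqs) % 2 == 0
    ids, haps = [], []
    for i in range(len(seqs)):
        ids.append(f"ind{i // 2 + 1}")
        haps.append(1 + i % 2)
    return PhasedAlignment(
        list(seqs), ids, haps, [population] * len(seqs), frame_offset=frame_offset
    )


def random_alignment(rng, n=None, L=None):
    """Random ACGT alignment with an even number of sequences."""
    n = n if n is not None else 2 * int(rng.integers(1, 7))
    L = L if L is not None else int(rng.integers(4, 40))
    mat = rng.choice(list("ACGT"), size=(n, L))
    return make_alignment(["".join(row) for row in mat])


def make_msat(genotype_rows, loci=None, populations=None):
    """Build an MsatDataset from a list of per-individual genotype lists,
    each genotype a (a, b) tuple or None for missing."""
    n = len(genotype_rows)
    m = len(genotype_rows[0])
    loci = loci or [f"L{j + 1}" for j in range(m)]
    geno = np.empty((n, m, 2), dtype=np.int64)
    for i, row in enumerate(genotype_rows):
        for j, g in enumerate(row):
            geno[i, j] = (-1, -1) if g is None else g
    return MsatDataset(
        individuals=[f"ind{i + 1}" for i in range(n)],
        loci=loci,
        genotypes=geno,
        populations=populations or ["pop"] * n,
    )


def brute_force_pi(alignment):
    """Independent oracle: mean per-site difference over all unordered
    sequence pairs, by direct double loop over raw strings."""
    seqs = alignment.sequences
    n = len(seqs)
    L = len(seqs[0])
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return total / (n * (n - 1) / 2) / L


@pytest.fixture
def toy_two_pair_alignment():
    """4 sequences = two identical pairs differing at 2 of 100 sites."""
    base = "A" * 100
    var = "T" + "A" * 98 + "T"
    return make_alignment([base, base, var, var])
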