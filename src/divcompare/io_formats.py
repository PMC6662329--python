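"""Input/output for the four data formats the analysis consumes.

Domain containers
-----------------
:class:`PhasedAlignment`
    Equal-length, in-frame haplotype sequences, two per diploid individual,
    each carrying a population label.
:class:`CodonPartition`
    The peptide-binding-region (PBR) / non-PBR split of the amplicon codons.
:class:`MsatDataset`
    Diploid multiallelic microsatellite genotypes (individuals x loci) with
    an explicit missing-data mask.
Metadata (individual id, population, sex, age class) travels as a validated
:class:`pandas.DataFrame`.

All downstream modules consume only these containers; the readers validate
their invariants eagerly so estimator code never re-checks file structure.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    BoundsError,
    FormatError,
    PairingError,
    VocabularyError,
)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN-")
SEXES = ("male", "female", "unknown")
AGE_CLASSES = ("calf", "juvenile", "adult", "unknown")

#: default header convention: ``<individual>_hap1`` / ``<individual>_hap2``
DEFAULT_HEADER_REGEX = re.compile(r"^(?P<ind>.+)_hap(?P<hap>[12])$")


@dataclass
class PhasedAlignment:
    """Phased haplotype alignment with two sequences per diploid individual.

    Parameters
    ----------
    sequences
        Upper-case nucleotide strings, all of equal length ``L``.
    individual_ids, haplotype_index, populations
        Parallel per-sequence annotations. ``haplotype_index`` is 1 or 2.
    frame_offset
        0-based alignment position of the first complete codon.
    """

    sequences: list[str]
    individual_ids: list[str]
    haplotype_index: list[int]
    populations: list[str]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.sequences = [s.upper() for s in self.sequences]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.sequences:
            raise FormatError("alignment contains no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
        n = len(self.sequences)
        for name in ("individual_ids", "haplotype_index", "populations"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"{name} length does not match sequence count")
        bad = set("".join(self.sequences)) - NUCLEOTIDE_ALPHABET
        if bad:
            raise AlphabetError(f"illegal characters in alignment: {sorted(bad)}")
        if self.L - self.frame_offset < 3:
            raise FormatError("fewer than one complete codon after frame offset")
        counts: dict[str, list[int]] = {}
        for ind, hap in zip(self.individual_ids, self.haplotype_index):
            counts.setdefault(ind, []).append(hap)
        for ind, haps in counts.items():
            if sorted(haps) != [1, 2]:
                raise PairingError(
                    f"individual {ind!r} has haplotype indices {sorted(haps)}, "
                    "expected exactly [1, 2]"
                )

    # -- basic views ------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of haplotype copies (2 x individuals)."""
        return len(self.sequences)

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(ind)
        return list(seen)

    def as_matrix(self) -> np.ndarray:
        """Alignment as a (n, L) byte matrix for vectorised column work."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype="S1"
        ).reshape(self.n, self.L)

    def subset_individuals(self, ids: Iterable[str]) -> "PhasedAlignment":
        wanted = set(ids)
        idx = [i for i, ind in enumerate(self.individual_ids) if ind in wanted]
        missing = wanted - {self.individual_ids[i] for i in idx}
        if missing:
            raise KeyError(f"individuals absent from alignment: {sorted(missing)}")
        return PhasedAlignment(
            sequences=[self.sequences[i] for i in idx],
            individual_ids=[self.individual_ids[i] for i in idx],
            haplotype_index=[self.haplotype_index[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            frame_offset=self.frame_offset,
        )

    def subset_population(self, population: str) -> "PhasedAlignment":
        ids = [
            ind
            for ind, pop in zip(self.individual_ids, self.populations)
            if pop == population
        ]
        if not ids:
            raise KeyError(f"no individuals in population {population!r}")
        return self.subset_individuals(ids)


@dataclass(frozen=True)
class CodonPartition:
    """PBR / non-PBR split of the 1-based codon indices of the amplicon."""

    pbr_codons: frozenset[int]
    total_codons: int

    def __post_init__(self) -> None:
        if self.total_codons < 1:
            raise BoundsError("total_codons must be >= 1")
        out = [c for c in self.pbr_codons if not 1 <= c <= self.total_codons]
        if out:
            raise BoundsError(
                f"codon indices out of range 1..{self.total_codons}: {sorted(out)}"
            )

    @property
    def n_pbr(self) -> int:
        return len(self.pbr_codons)

    @property
    def n_non_pbr(self) -> int:
        return self.total_codons - len(self.pbr_codons)

    def codons_for(self, site_class: str) -> list[int]:
        """1-based codon indices for ``site_class`` in {'pbr','nonpbr','all'}."""
        if site_class == "pbr":
            return sorted(self.pbr_codons)
        if site_class == "nonpbr":
            return [
                c for c in range(1, self.total_codons + 1) if c not in self.pbr_codons
            ]
        if site_class == "all":
            return list(range(1, self.total_codons + 1))
        raise ValueError(f"unknown site class {site_class!r}")


MISSING_ALLELE = -1  # internal placeholder only; masked everywhere


@dataclass
class MsatDataset:
    """Diploid microsatellite genotypes for one or more populations.

    ``genotypes`` has shape (n_individuals, n_loci, 2) with positive integer
    allele labels; missing genotypes hold the internal placeholder and are
    exposed only through :attr:`missing_mask`.
    """

    individuals: list[str]
    loci: list[str]
    genotypes: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.genotypes.shape != (n, m, 2):
            raise FormatError(
                f"genotype array shape {self.genotypes.shape} != ({n}, {m}, 2)"
            )
        if len(set(self.individuals)) != n:
            raise FormatError("duplicate individual ids")
        if len(self.populations) != n:
            raise FormatError("population labels do not match individual count")
        typed = self.genotypes[~self.missing_mask()]
        if typed.size and typed.min() < 1:
            raise FormatError("allele labels must be positive integers")
        half = (self.genotypes == MISSING_ALLELE).sum(axis=2)
        if np.any(half == 1):
            raise FormatError("half-missing genotype (one allele typed)")

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the genotype is missing."""
        return (self.genotypes == MISSING_ALLELE).any(axis=2)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def subset_individuals(self, ids: Iterable[str]) -> "MsatDataset":
        wanted = list(ids)
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        missing = [i for i in wanted if i not in pos]
        if missing:
            raise KeyError(f"individuals absent from dataset: {missing}")
        idx = [pos[i] for i in wanted]
        return MsatDataset(
            individuals=wanted,
            loci=list(self.loci),
            genotypes=self.genotypes[idx],
            populations=[self.populations[i] for i in idx],
        )

    def subset_population(self, population: str) -> "MsatDataset":
        ids = [
            ind
            for ind, pop in zip(self.individuals, self.populations)
            if pop == population
        ]
        if not ids:
            raise KeyError(f"no individuals in population {population!r}")
        return self.subset_individuals(ids)

    def subset_loci(self, loci: Sequence[str]) -> "MsatDataset":
        idx = [self.locus_index(l) for l in loci]
        return MsatDataset(
            individuals=list(self.individuals),
            loci=list(loci),
            genotypes=self.genotypes[:, idx, :],
            populations=list(self.populations),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_phased_fasta(
    path: str | Path,
    frame_offset: int = 0,
    header_regex: re.Pattern | str = DEFAULT_HEADER_REGEX,
    population_map: dict[str, str] | None = None,
    default_population: str = "pop",
) -> PhasedAlignment:
    """Read a phased haplotype FASTA.

    Headers follow ``<individual>_hap1`` / ``<individual>_hap2`` by default;
    pass ``header_regex`` with named groups ``ind`` and ``hap`` to override.
    Population labels come from ``population_map`` (individual id -> label)
    or fall back to ``default_population``.
    """
    pattern = re.compile(header_regex) if isinstance(header_regex, str) else header_regex
    sequences, ids, haps, pops = [], [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(rec.id)
        if not m:
            raise FormatError(
                f"header {rec.id!r} does not match the phasing convention "
                f"{pattern.pattern!r}"
            )
        ind = m.group("ind")
        sequences.append(str(rec.seq).upper())
        ids.append(ind)
        haps.append(int(m.group("hap")))
        pops.append(
            population_map.get(ind, default_population)
            if population_map
            else default_population
        )
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return PhasedAlignment(sequences, ids, haps, pops, frame_offset=frame_offset)


def write_phased_fasta(alignment: PhasedAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{ind}_hap{hap}", description="")
        for seq, ind, hap in zip(
            alignment.sequences, alignment.individual_ids, alignment.haplotype_index
        )
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_genotype_cell(cell: str, sep: str = "/"):
    cell = cell.strip()
    if cell in ("", "NA", "na", "?", "-", "0/0", "0"):
        return (MISSING_ALLELE, MISSING_ALLELE)
    parts = cell.split(sep)
    if len(parts) != 2:
        raise FormatError(f"genotype cell {cell!r} is not 'a{sep}b'")
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise FormatError(f"non-integer allele in genotype cell {cell!r}") from None
    if a < 1 or b < 1:
        raise FormatError(f"allele labels must be positive: {cell!r}")
    return (a, b)


def read_genotype_csv(path: str | Path, population_column: str = "population") -> MsatDataset:
    """Read a genotype table: columns ``id``, ``population``, then one
    ``a/b`` column per locus; empty cells are missing genotypes."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if "id" not in df.columns:
        raise FormatError("genotype CSV must have an 'id' column")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"duplicate individual ids: {dupes}")
    loci = [c for c in df.columns if c not in ("id", population_column)]
    if not loci:
        raise FormatError("genotype CSV contains no locus columns")
    pops = (
        df[population_column].tolist()
        if population_column in df.columns
        else ["pop"] * len(df)
    )
    geno = np.empty((len(df), len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for i, cell in enumerate(df[locus]):
            geno[i, j] = _parse_genotype_cell(cell)
    return MsatDataset(df["id"].tolist(), loci, geno, pops)


def write_genotype_csv(dataset: MsatDataset, path: str | Path) -> None:
    rows = []
    for i, ind in enumerate(dataset.individuals):
        row = {"id": ind, "population": dataset.populations[i]}
        for j, locus in enumerate(dataset.loci):
            a, b = dataset.genotypes[i, j]
            row[locus] = "" if a == MISSING_ALLELE else f"{a}/{b}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    """Read individual metadata (id, population, sex, age_class).

    Categories are a closed vocabulary; unmapped strings (e.g. ``F`` for
    female) raise :class:`VocabularyError` rather than being coerced.
    """
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    required = {"id", "population", "sex", "age_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata CSV missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        raise FormatError("duplicate individual ids in metadata")
    return validate_metadata(df[["id", "population", "sex", "age_class"]])


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise VocabularyError(
            f"unknown sex values {sorted(bad_sex)}; allowed: {SEXES}"
        )
    bad_age = set(df["age_class"]) - set(AGE_CLASSES)
    if bad_age:
        raise VocabularyError(
            f"unknown age_class values {sorted(bad_age)}; allowed: {AGE_CLASSES}"
        )
    return df.reset_index(drop=True)


def write_metadata_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_codon_partition(path: str | Path, total_codons: int) -> CodonPartition:
    """Read PBR codon indices from a JSON list or a one-index-per-line TSV."""
    text = Path(path).read_text().strip()
    if text.startswith("[") or text.startswith("{"):
        obj = json.loads(text)
        indices = obj["pbr_codons"] if isinstance(obj, dict) else obj
    else:
        indices = [int(tok) for tok in text.split()] if text else []
    return CodonPartition(frozenset(int(i) for i in indices), total_codons)


def write_codon_partition(partition: CodonPartition, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "pbr_codons": sorted(partition.pbr_codons),
                "total_codons": partition.total_codons,
            }
        )
        + "\n"
    )
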