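"""Genotype data model, FSTAT / delimited-table I/O, pooling and filtering.

The central container is :class:`GenotypeMatrix`: diploid individuals typed at
biallelic SNP loci, stored as reference-allele dosage (0, 1, 2) with ``-1``
marking a missing call.  All diversity and differentiation estimators in this
package are allele-frequency based, so phase is never stored.

The FSTAT dialect implemented here is the classic one consumed by hierfstat:
a header line ``np nl max_allele digits``, then ``nl`` locus-name lines, then
one row per individual consisting of a 1-based population index followed by
``nl`` genotype codes (two fixed-width allele codes concatenated; an all-zero
code is a missing call).  FSTAT files carry no individual ids and no
population names, so reading assigns labels ``pop1..popk`` and synthetic ids
``<pop>_<i>``; a write/read roundtrip is exact for matrices already in that
canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "LocusFilterSettings",
    "LocusFilterReport",
    "AlleleCounts",
    "ParseError",
    "EmptyResultError",
    "read_fstat",
    "write_fstat",
    "read_genotype_table",
    "write_genotype_table",
    "filter_individuals",
    "filter_loci",
    "pool_populations",
    "allele_counts",
]


class ParseError(ValueError):
    """Malformed input file (message names the offending line/cell)."""


class EmptyResultError(ValueError):
    """An operation removed every individual or every locus."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, diploid, with population labels.

    Parameters
    ----------
    individual_ids
        Unique identifier per individual (row).
    populations
        One population label per individual.
    genotypes
        ``(n_individuals, n_loci)`` integer array of reference-allele dosages
        in ``{0, 1, 2}`` with :data:`MISSING` (-1) for no call.
    locus_ids
        Unique identifier per locus (column).
    """

    individual_ids: list[str]
    populations: list[str]
    genotypes: np.ndarray
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.populations = [str(x) for x in self.populations]
        self.locus_ids = [str(x) for x in self.locus_ids]
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        n, l = self.genotypes.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match genotypes")
        if len(self.populations) != n:
            raise ValueError("populations length does not match genotypes")
        if len(self.locus_ids) != l:
            raise ValueError("locus_ids length does not match genotypes")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        if len(set(self.locus_ids)) != l:
            raise ValueError("locus_ids must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.genotypes[i, j]} for individual "
                f"{self.individual_ids[i]!r} at locus {self.locus_ids[j]!r}"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def population_names(self) -> list[str]:
        """Unique population labels, in order of first appearance."""
        return list(dict.fromkeys(self.populations))

    def population_mask(self, label: str) -> np.ndarray:
        mask = np.asarray([p == label for p in self.populations])
        if not mask.any():
            raise KeyError(f"no such population: {label!r}")
        return mask

    def subset(
        self,
        individuals: Sequence[int] | np.ndarray | None = None,
        loci: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Positional subset along either axis; order follows the indexer."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        ind = np.flatnonzero(ind) if ind.dtype == bool else ind.astype(np.intp)
        loc = np.flatnonzero(loc) if loc.dtype == bool else loc.astype(np.intp)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in ind],
            [self.populations[i] for i in ind],
            self.genotypes[np.ix_(ind, loc)],
            [self.locus_ids[j] for j in loc],
        )

    def missing_fraction_per_individual(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.populations == other.populations
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class LocusFilterSettings:
    """Locus filter thresholds; a value of 0 / False disables the criterion.

    ``maf_min`` is a pooled minor-allele-frequency floor (loci with MAF
    strictly below it are removed), ``per_pop_presence_min`` the minimum
    fraction of typed individuals within every population, and
    ``overall_presence_min`` the minimum typed fraction over all individuals.
    ``one_snp_per_locus`` keeps the first SNP per RAD-locus group when the
    locus ids carry a ``<group>_<n>`` key; with independent loci it is a
    no-op.
    """

    maf_min: float = 0.0
    per_pop_presence_min: float = 0.0
    overall_presence_min: float = 0.0
    max_individual_missing: float = 1.0
    one_snp_per_locus: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_min", "per_pop_presence_min", "overall_presence_min",
                     "max_individual_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class LocusFilterReport:
    """Counts of loci removed per criterion, in the order applied."""

    n_input: int
    removed_one_snp: list[str] = field(default_factory=list)
    removed_per_pop_presence: list[str] = field(default_factory=list)
    removed_overall_presence: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_input - sum(
            len(x) for x in (self.removed_one_snp, self.removed_per_pop_presence,
                             self.removed_overall_presence, self.removed_maf)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage, ids in (
            ("one_snp_per_locus", self.removed_one_snp),
            ("per_pop_presence", self.removed_per_pop_presence),
            ("overall_presence", self.removed_overall_presence),
            ("maf", self.removed_maf),
        ):
            rows.extend({"criterion": stage, "locus": x} for x in ids)
        return pd.DataFrame(rows, columns=["criterion", "locus"])


# ---------------------------------------------------------------------------
# FSTAT I/O


def read_fstat(path) -> GenotypeMatrix:
    """Read an FSTAT genotype file into a :class:`GenotypeMatrix`.

    Allele codes are mapped to reference dosage: code 1 is the reference
    allele when present at a locus (the convention :func:`write_fstat` emits);
    otherwise the smallest observed code is taken as reference.  A code of
    width-matched zeros is a missing call.  More than two distinct allele
    codes at a locus is an error (loci must be biallelic).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) != 4:
        raise ParseError(f"{path}, line 1: header must have 4 fields, got {len(header)}")
    try:
        n_pop, n_loci, max_allele, digits = (int(x) for x in header)
    except ValueError as exc:
        raise ParseError(f"{path}, line 1: non-integer header field ({exc})") from None
    if digits < 1 or max_allele < 1 or n_pop < 1 or n_loci < 1:
        raise ParseError(f"{path}, line 1: invalid header values {header}")
    if len(lines) < 1 + n_loci:
        raise ParseError(f"{path}: expected {n_loci} locus names, file too short")
    locus_ids = [lines[1 + i].strip() for i in range(n_loci)]

    rows = lines[1 + n_loci:]
    if not rows:
        raise ParseError(f"{path}: no genotype rows")
    a1 = np.empty((len(rows), n_loci), dtype=np.int32)
    a2 = np.empty((len(rows), n_loci), dtype=np.int32)
    pop_idx = np.empty(len(rows), dtype=np.int32)
    for r, row in enumerate(rows):
        lineno = 2 + n_loci + r
        parts = row.split()
        if len(parts) != 1 + n_loci:
            raise ParseError(
                f"{path}, line {lineno}: expected {1 + n_loci} fields, got {len(parts)}"
            )
        try:
            k = int(parts[0])
        except ValueError:
            raise ParseError(f"{path}, line {lineno}: bad population index {parts[0]!r}") from None
        if not 1 <= k <= n_pop:
            raise ParseError(f"{path}, line {lineno}: population index {k} outside 1..{n_pop}")
        pop_idx[r] = k
        for j, code in enumerate(parts[1:]):
            if len(code) != 2 * digits or not code.isdigit():
                raise ParseError(
                    f"{path}, line {lineno}: genotype code {code!r} is not "
                    f"{2 * digits} digits"
                )
            a1[r, j] = int(code[:digits])
            a2[r, j] = int(code[digits:])

    genotypes = np.empty((len(rows), n_loci), dtype=np.int8)
    for j in range(n_loci):
        c1, c2 = a1[:, j], a2[:, j]
        half_missing = (c1 == 0) != (c2 == 0)
        if half_missing.any():
            r = int(np.flatnonzero(half_missing)[0])
            raise ParseError(
                f"{path}, line {2 + n_loci + r}: half-missing genotype at locus "
                f"{locus_ids[j]!r}"
            )
        missing = c1 == 0
        observed = np.unique(np.concatenate([c1[~missing], c2[~missing]]))
        if observed.size > 2:
            raise ParseError(
                f"{path}: locus {locus_ids[j]!r} has {observed.size} alleles; "
                "loci must be biallelic"
            )
        # allele code 1 is the reference whenever codes follow the 1/2
        # convention (even if only code 2 appears); nonstandard code sets
        # fall back to smallest-code-as-reference.
        ref = 1 if set(observed.tolist()) <= {1, 2} else int(observed.min())
        genotypes[:, j] = (c1 == ref).astype(np.int8) + (c2 == ref).astype(np.int8)
        genotypes[missing, j] = MISSING

    populations = [f"pop{k}" for k in pop_idx]
    counts: dict[str, int] = {}
    individual_ids = []
    for p in populations:
        counts[p] = counts.get(p, 0) + 1
        individual_ids.append(f"{p}_{counts[p]}")
    return GenotypeMatrix(individual_ids, populations, genotypes, locus_ids)


def write_fstat(gm: GenotypeMatrix, path) -> None:
    """Write ``gm`` as an FSTAT file (allele 1 = reference, 2 = alternate).

    Rows are ordered by population label then individual id so output is
    deterministic regardless of input order.  Population names and individual
    ids are not representable in the format; see :func:`read_fstat`.
    """
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise EmptyResultError("refusing to write an empty genotype matrix")
    pops = sorted(set(gm.populations))
    pop_number = {p: i + 1 for i, p in enumerate(pops)}
    order = sorted(range(gm.n_individuals),
                   key=lambda i: (gm.populations[i], gm.individual_ids[i]))
    code = {2: "11", 1: "12", 0: "22", MISSING: "00"}
    with open(path, "w") as fh:
        fh.write(f"{len(pops)} {gm.n_loci} 2 1\n")
        for locus in gm.locus_ids:
            fh.write(f"{locus}\n")
        for i in order:
            row = gm.genotypes[i]
            fh.write(" ".join([str(pop_number[gm.populations[i]])]
                              + [code[int(d)] for d in row]) + "\n")


# ---------------------------------------------------------------------------
# Delimited genotype tables


def read_genotype_table(path, sep: str = "\t") -> GenotypeMatrix:
    """Read a delimited table: individual, population, one column per locus.

    Cells must be 0/1/2 or ``NA`` (missing); anything else is a
    :class:`ParseError` naming the offending cell.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: need individual, population and >=1 locus column")
    ind_col, pop_col = df.columns[:2]
    locus_ids = list(df.columns[2:])
    genotypes = np.empty((len(df), len(locus_ids)), dtype=np.int8)
    for j, locus in enumerate(locus_ids):
        col = df[locus].astype(str).str.strip()
        for r, v in enumerate(col):
            if v in ("NA", "nan", ""):
                genotypes[r, j] = MISSING
            elif v in ("0", "1", "2"):
                genotypes[r, j] = int(v)
            else:
                raise ParseError(
                    f"{path}: invalid genotype {v!r} at row {r + 2}, column {locus!r}"
                )
    return GenotypeMatrix(list(df[ind_col]), list(df[pop_col]), genotypes, locus_ids)


def write_genotype_table(gm: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Lossless inverse of :func:`read_genotype_table` (column order = locus order)."""
    data = {"individual": gm.individual_ids, "population": gm.populations}
    for j, locus in enumerate(gm.locus_ids):
        col = gm.genotypes[:, j].astype(object)
        data[locus] = ["NA" if v == MISSING else str(v) for v in col]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Filters and pooling


def filter_individuals(
    gm: GenotypeMatrix, max_missing: float
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals whose missing-call fraction exceeds ``max_missing``.

    Returns the filtered matrix and the list of removed individual ids.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = gm.missing_fraction_per_individual()
    keep = frac <= max_missing
    if not keep.any():
        raise EmptyResultError("individual filter removed every individual")
    removed = [gm.individual_ids[i] for i in np.flatnonzero(~keep)]
    return gm.subset(individuals=keep), removed


def _one_snp_groups(locus_ids: Sequence[str]) -> np.ndarray:
    """Keep-mask retaining the first SNP per ``<group>_<n>`` locus-id group."""
    import re

    keep = np.ones(len(locus_ids), dtype=bool)
    seen: set[str] = set()
    for j, locus in enumerate(locus_ids):
        m = re.fullmatch(r"(.+)_(\d+)", locus)
        group = m.group(1) if m else locus
        if group in seen:
            keep[j] = False
        else:
            seen.add(group)
    return keep


def filter_loci(
    gm: GenotypeMatrix, settings: LocusFilterSettings
) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Apply locus filters in a fixed, reported order.

    Order: one-SNP-per-locus (if enabled), per-population presence, overall
    presence, pooled minor allele frequency.  MAF is computed on non-missing
    calls pooled over all individuals.
    """
    report = LocusFilterReport(n_input=gm.n_loci)
    keep = np.ones(gm.n_loci, dtype=bool)
    geno = gm.genotypes
    typed = geno != MISSING

    if settings.one_snp_per_locus:
        k = _one_snp_groups(gm.locus_ids)
        report.removed_one_snp = [gm.locus_ids[j] for j in np.flatnonzero(keep & ~k)]
        keep &= k

    if settings.per_pop_presence_min > 0:
        k = np.ones(gm.n_loci, dtype=bool)
        for pop in gm.population_names:
            mask = gm.population_mask(pop)
            presence = typed[mask].mean(axis=0)
            k &= presence >= settings.per_pop_presence_min
        report.removed_per_pop_presence = [
            gm.locus_ids[j] for j in np.flatnonzero(keep & ~k)
        ]
        keep &= k

    if settings.overall_presence_min > 0:
        k = typed.mean(axis=0) >= settings.overall_presence_min
        report.removed_overall_presence = [
            gm.locus_ids[j] for j in np.flatnonzero(keep & ~k)
        ]
        keep &= k

    if settings.maf_min > 0:
        n_typed = typed.sum(axis=0)
        ref = np.where(typed, geno, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ref / (2.0 * n_typed)
        maf = np.minimum(p, 1.0 - p)
        maf[n_typed == 0] = 0.0
        k = maf >= settings.maf_min
        report.removed_maf = [gm.locus_ids[j] for j in np.flatnonzero(keep & ~k)]
        keep &= k

    if not keep.any():
        raise EmptyResultError("locus filter removed every locus")
    return gm.subset(loci=keep), report


def pool_populations(gm: GenotypeMatrix, pooling: Mapping[str, str]) -> GenotypeMatrix:
    """Replace fine-grained site labels by coarse labels (genotypes untouched).

    Every population label present in ``gm`` must be mapped; an unmapped label
    raises ``KeyError`` naming it.
    """
    for p in gm.population_names:
        if p not in pooling:
            raise KeyError(f"population {p!r} missing from pooling map")
    return GenotypeMatrix(
        list(gm.individual_ids),
        [str(pooling[p]) for p in gm.populations],
        gm.genotypes.copy(),
        list(gm.locus_ids),
    )


# ---------------------------------------------------------------------------
# Allele counts


@dataclass
class AlleleCounts:
    """Per-population, per-locus allele counts.

    ``copies`` is twice the number of typed individuals; ``ref + alt ==
    copies`` holds in every cell.
    """

    populations: list[str]
    locus_ids: list[str]
    ref: np.ndarray     # (n_pops, n_loci)
    copies: np.ndarray  # (n_pops, n_loci)

    @property
    def alt(self) -> np.ndarray:
        return self.copies - self.ref

    def frequencies(self) -> np.ndarray:
        """Reference-allele frequency; NaN where a population has no calls."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.copies > 0, self.ref / self.copies, np.nan)


def allele_counts(gm: GenotypeMatrix) -> AlleleCounts:
    pops = gm.population_names
    ref = np.zeros((len(pops), gm.n_loci), dtype=np.int64)
    copies = np.zeros_like(ref)
    typed = gm.genotypes != MISSING
    for i, pop in enumerate(pops):
        mask = gm.population_mask(pop)
        g = gm.genotypes[mask]
        t = typed[mask]
        copies[i] = 2 * t.sum(axis=0)
        ref[i] = np.where(t, g, 0).sum(axis=0)
    return AlleleCounts(pops, list(gm.locus_ids), ref, copies)
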