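"""Diversity and differentiation estimators for biallelic SNP matrices.

Implements the frequency-based statistic stack used throughout the package:

* observed heterozygosity H_O, within-population gene diversity H_S
  (small-sample corrected, ``2n/(2n-1)``), total gene diversity H_T from mean
  allele frequencies, and the inbreeding coefficient F_IS = 1 - H_O/H_S;
* Weir & Cockerham's theta (multi-locus ratio of variance-component sums,
  negative estimates reported as-is) with bootstrap-over-loci percentile
  confidence intervals;
* Nei's G_ST from allele frequencies (no sample-size correction);
* rarefied allelic richness via hypergeometric subsampling to a standard
  number of gene copies;
* private-allele counts with population subsampling to the smallest size;
* a seedable one-sided Mantel permutation test.

Missing data are handled per locus: every estimator uses the typed gene-copy
count of each population at each locus, and loci with fewer than two typed
populations contribute nothing to multi-population statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import MISSING, GenotypeMatrix, allele_counts

__all__ = [
    "DiversityStats",
    "FstResult",
    "RichnessResult",
    "PrivateAlleleResult",
    "diversity_stats",
    "wc_fst",
    "wc_fst_components",
    "pairwise_fst_matrix",
    "bootstrap_fst_ci",
    "nei_gst",
    "allelic_richness",
    "private_alleles",
    "mantel_test",
]


# ---------------------------------------------------------------------------
# Per-population summaries


def _pop_summaries(gm: GenotypeMatrix, populations=None):
    """Typed counts, reference frequencies and heterozygote frequencies.

    Returns ``(pops, n, p, h)`` with arrays of shape ``(n_pops, n_loci)``;
    ``p`` and ``h`` are NaN where a population has no typed individual.
    """
    pops = gm.population_names if populations is None else list(populations)
    for pop in pops:
        gm.population_mask(pop)  # raises on unknown label
    n = np.zeros((len(pops), gm.n_loci))
    p = np.full_like(n, np.nan)
    h = np.full_like(n, np.nan)
    for i, pop in enumerate(pops):
        g = gm.genotypes[gm.population_mask(pop)]
        typed = g != MISSING
        ni = typed.sum(axis=0)
        n[i] = ni
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(ni > 0, np.where(typed, g, 0).sum(axis=0) / (2.0 * ni), np.nan)
            h[i] = np.where(ni > 0, (g == 1).sum(axis=0) / ni, np.nan)
    return pops, n, p, h


# ---------------------------------------------------------------------------
# Gene diversities


@dataclass
class DiversityStats:
    """Per-locus and across-locus gene diversity summaries.

    ``ho``/``hs`` have shape ``(n_pops, n_loci)``; ``ht`` has shape
    ``(n_loci,)``.  ``fis`` is per population across loci, NaN where H_S is 0
    (monomorphic within the population).
    """

    populations: list[str]
    locus_ids: list[str]
    ho: np.ndarray
    hs: np.ndarray
    ht: np.ndarray
    ho_mean: pd.Series
    hs_mean: pd.Series
    ht_mean: float
    fis: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (population, locus, statistic, value)."""
        rows = []
        for i, pop in enumerate(self.populations):
            for j, locus in enumerate(self.locus_ids):
                rows.append((pop, locus, "ho", self.ho[i, j]))
                rows.append((pop, locus, "hs", self.hs[i, j]))
        for j, locus in enumerate(self.locus_ids):
            rows.append(("_all_", locus, "ht", self.ht[j]))
        return pd.DataFrame(rows, columns=["population", "locus", "statistic", "value"])


def diversity_stats(gm: GenotypeMatrix, populations=None) -> DiversityStats:
    """H_O, H_S, H_T and F_IS.

    H_S uses the unbiased within-population gene diversity
    ``2n/(2n-1) * (1 - p^2 - q^2)``; H_T is computed from the unweighted mean
    of population allele frequencies without further correction, so
    H_S <= H_T holds up to sample-size noise.  F_IS = 1 - H_O/H_S from
    across-locus means, NaN when H_S is zero.
    """
    pops, n, p, h = _pop_summaries(gm, populations)
    with np.errstate(invalid="ignore", divide="ignore"):
        gene_div = 2.0 * p * (1.0 - p)
        hs = gene_div * (2.0 * n) / (2.0 * n - 1.0)
    hs[n < 1] = np.nan
    # populations with a single typed individual have an undefined unbiased
    # diversity denominator only at n=0.5, not here: 2n/(2n-1)=2 at n=1.
    pbar = np.nanmean(p, axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)
    ho_mean = pd.Series(np.nanmean(h, axis=1), index=pops)
    hs_mean = pd.Series(np.nanmean(hs, axis=1), index=pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        fis = 1.0 - ho_mean / hs_mean
    fis[hs_mean == 0] = np.nan
    return DiversityStats(
        populations=pops,
        locus_ids=list(gm.locus_ids),
        ho=h,
        hs=hs,
        ht=ht,
        ho_mean=ho_mean,
        hs_mean=hs_mean,
        ht_mean=float(np.nanmean(ht)),
        fis=fis,
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham theta


def wc_fst_components(gm: GenotypeMatrix, populations=None):
    """Per-locus Weir–Cockerham variance components ``(a, b, c)``.

    Components follow the two-allele variance decomposition: ``a`` is the
    among-population component, ``b`` among individuals within populations,
    ``c`` within individuals.  Loci where fewer than two populations are
    typed, or where the mean sample size does not exceed one, are set to zero
    in all three components (they contribute nothing to the ratio of sums).
    """
    pops, n, p, h = _pop_summaries(gm, populations)
    if len(pops) < 2:
        raise ValueError("Weir-Cockerham theta needs at least two populations")
    typed = n > 0
    r = typed.sum(axis=0).astype(float)

    n0 = np.where(typed, n, 0.0)
    p0 = np.where(typed, np.nan_to_num(p), 0.0)
    h0 = np.where(typed, np.nan_to_num(h), 0.0)

    n_sum = n0.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        pbar = (n0 * p0).sum(axis=0) / n_sum
        hbar = (n0 * h0).sum(axis=0) / n_sum
        nc = (n_sum - (n0**2).sum(axis=0) / n_sum) / (r - 1.0)
        s2 = (n0 * (p0 - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)

        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0

    valid = (r >= 2) & (nbar > 1.0) & (nc > 0)
    for arr in (a, b, c):
        arr[~valid] = 0.0
        np.nan_to_num(arr, copy=False)
    if not valid.any():
        raise ValueError("no locus is typed in two or more populations")
    return a, b, c


def wc_fst(gm: GenotypeMatrix, populations=None) -> float:
    """Multi-locus Weir–Cockerham theta as a ratio of component sums.

    Negative estimates are reported as-is.  ``populations`` restricts the
    estimate to a subset (e.g. one pair); by default all populations enter.
    """
    a, b, c = wc_fst_components(gm, populations)
    denom = (a + b + c).sum()
    if denom == 0:
        return np.nan
    return float(a.sum() / denom)


def pairwise_fst_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric matrix of pairwise theta over all population pairs, diagonal 0."""
    pops = gm.population_names
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            theta = wc_fst(gm, populations=[pops[i], pops[j]])
            out.iloc[i, j] = out.iloc[j, i] = theta
    return out


@dataclass
class FstResult:
    """Point estimate with a bootstrap-over-loci percentile interval.

    ``significant`` follows the rule that differentiation is supported when
    the lower confidence bound exceeds zero.
    """

    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int

    @property
    def significant(self) -> bool:
        return bool(self.ci_low > 0)


def bootstrap_fst_ci(
    gm: GenotypeMatrix,
    pair=None,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> FstResult:
    """Bootstrap loci with replacement and recompute the ratio-of-sums theta.

    The percentile interval uses the 0.025/0.975 quantiles by default
    (``alpha=0.05``).  Deterministic given ``seed``.  Requires at least two
    loci (a single locus admits no across-locus resampling).
    """
    if gm.n_loci < 2:
        raise ValueError("bootstrap CI needs >= 2 loci")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    a, b, c = wc_fst_components(gm, pair)
    abc = a + b + c
    total = abc.sum()
    estimate = float(a.sum() / total) if total != 0 else np.nan

    rng = np.random.default_rng(seed)
    L = a.size
    idx = rng.integers(0, L, size=(n_boot, L))
    num = a[idx].sum(axis=1)
    den = abc[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = np.where(den != 0, num / den, np.nan)
    lo, hi = np.nanpercentile(thetas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return FstResult(estimate=estimate, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


# ---------------------------------------------------------------------------
# Nei's G_ST


def nei_gst(p: np.ndarray) -> float:
    """Nei's G_ST from per-population reference-allele frequencies.

    ``p`` has shape ``(n_pops, n_loci)`` (or ``(n_pops,)`` for one locus).
    Populations are weighted equally and no sample-size correction is
    applied: per locus, H_S is the mean of ``2 p q`` and H_T is ``2 p̄ q̄``
    with the unweighted mean frequency.  The multi-locus value sums H_T and
    H_S over loci.  All-monomorphic input (H_T = 0) is defined as 0.
    NaN frequencies (untyped population-locus cells) drop that population
    from the locus.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    hs = np.nanmean(2.0 * p * (1.0 - p), axis=0)
    pbar = np.nanmean(p, axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)
    ok = ~np.isnan(ht)
    ht_sum = ht[ok].sum()
    if ht_sum == 0:
        return 0.0
    return float((ht_sum - hs[ok].sum()) / ht_sum)


# ---------------------------------------------------------------------------
# Allelic richness (rarefaction)


@dataclass
class RichnessResult:
    """Rarefied allelic richness at a standard sample of ``g`` gene copies."""

    populations: list[str]
    locus_ids: list[str]
    g: int
    per_locus: np.ndarray  # (n_pops, n_loci), NaN where copies < g
    mean: pd.Series


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def allelic_richness(gm: GenotypeMatrix, g: int | None = None) -> RichnessResult:
    """Expected allele count in a hypergeometric subsample of ``g`` copies.

    Per population and locus with ``N`` typed gene copies of which ``N_a``
    carry allele ``a``:  ``AR = sum_a [1 - C(N - N_a, g) / C(N, g)]``.  The
    default ``g`` is the smallest typed gene-copy count over all population x
    locus cells with at least one call.  Cells with fewer than ``g`` copies
    are NaN and excluded from the across-locus mean.
    """
    counts = allele_counts(gm)
    copies = counts.copies.astype(float)
    if g is None:
        nonzero = copies[copies > 0]
        if nonzero.size == 0:
            raise ValueError("no typed calls in matrix")
        g = int(nonzero.min())
    if g < 2:
        raise ValueError(f"rarefaction size g must be >= 2, got {g}")

    per_locus = np.full(copies.shape, np.nan)
    ok = copies >= g
    logCNg = np.where(ok, _log_comb(np.maximum(copies, g), g), np.nan)
    total = np.zeros(copies.shape)
    for allele in (counts.ref, counts.alt):
        rest = copies - allele
        with np.errstate(invalid="ignore"):
            term = np.where(rest >= g, np.exp(_log_comb(np.maximum(rest, g), g) - logCNg), 0.0)
        total += 1.0 - term
    per_locus[ok] = total[ok]
    mean = pd.Series(np.nanmean(per_locus, axis=1), index=counts.populations)
    return RichnessResult(counts.populations, counts.locus_ids, g, per_locus, mean)


# ---------------------------------------------------------------------------
# Private alleles


@dataclass
class PrivateAlleleResult:
    mean_private: pd.Series
    n_replicates: int
    target_size: int
    per_replicate: np.ndarray  # (n_replicates, n_pops)


def private_alleles(
    gm: GenotypeMatrix, n_reps: int = 30, seed: int | None = None
) -> PrivateAlleleResult:
    """Mean private-allele count per population under size-matched subsampling.

    A private allele is present (frequency > 0) in exactly one population.
    Populations larger than the smallest one are subsampled without
    replacement to that size in each replicate; with equal sizes every
    replicate is identical.  Deterministic given ``seed``.
    """
    pops = gm.population_names
    if len(pops) < 2:
        raise ValueError("private alleles need >= 2 populations")
    rng = np.random.default_rng(seed)
    indices = {p: np.flatnonzero(gm.population_mask(p)) for p in pops}
    target = min(len(v) for v in indices.values())

    counts = np.zeros((n_reps, len(pops)))
    for rep in range(n_reps):
        present = np.zeros((len(pops), gm.n_loci, 2), dtype=bool)
        for i, pop in enumerate(pops):
            idx = indices[pop]
            if len(idx) > target:
                idx = rng.choice(idx, size=target, replace=False)
            g = gm.genotypes[idx]
            typed = g != MISSING
            ref = np.where(typed, g, 0).sum(axis=0)
            copies = 2 * typed.sum(axis=0)
            present[i, :, 0] = ref > 0
            present[i, :, 1] = (copies - ref) > 0
        n_carriers = present.sum(axis=0)
        private = present & (n_carriers == 1)[None, :, :]
        counts[rep] = private.sum(axis=(1, 2))
    return PrivateAlleleResult(
        mean_private=pd.Series(counts.mean(axis=0), index=pops),
        n_replicates=n_reps,
        target_size=target,
        per_replicate=counts,
    )


# ---------------------------------------------------------------------------
# Mantel test


def _as_square(d) -> tuple[list[str], np.ndarray]:
    if isinstance(d, pd.DataFrame):
        return list(d.index), d.to_numpy(dtype=float)
    arr = np.asarray(d, dtype=float)
    return [str(i) for i in range(arr.shape[0])], arr


def mantel_test(
    dist_a,
    dist_b,
    n_perm: int = 9_999,
    seed: int | None = None,
    one_sided: bool = True,
) -> tuple[float, float]:
    """Mantel permutation test between two labelled distance matrices.

    ``r`` is the Pearson correlation of the lower-triangle entries; ``p`` is
    ``(count(r_perm >= r_obs) + 1) / (n_perm + 1)`` for the one-sided
    (positive-association) test, with ``|r_perm| >= |r_obs|`` two-sided.
    DataFrames are aligned on labels; label mismatch is an error, as is a
    matrix with zero variance off-diagonal (r undefined).
    """
    la, a = _as_square(dist_a)
    lb, b = _as_square(dist_b)
    if set(la) != set(lb):
        raise ValueError("distance matrices have mismatched labels")
    if isinstance(dist_b, pd.DataFrame):
        b = dist_b.loc[la, la].to_numpy(dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and the same size")
    for name, m in (("dist_a", a), ("dist_b", b)):
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError(f"{name} is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError(f"{name} has a nonzero diagonal")

    n = a.shape[0]
    tri = np.tril_indices(n, k=-1)
    x = a[tri]
    if np.std(x) == 0 or np.std(b[tri]) == 0:
        raise ValueError("zero variance in distances: Mantel r undefined")

    def corr(m: np.ndarray) -> float:
        y = m[tri]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(b[np.ix_(perm, perm)])
        if one_sided:
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)
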