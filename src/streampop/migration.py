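"""Directional relative migration networks from genotype matrices.

For every ordered population pair (i, j) a hypothetical migrant pool is
formed with the unweighted mean of the two populations' allele frequencies.
Nei's G_ST between the *recipient* population and that pool measures how much
the recipient has diverged from the shared migrant gene pool: a population
receiving many migrants resembles the pool and shows low differentiation.
The differentiation d is converted to an effective-migrant estimate through
Nm = ((1/d) - 1)/4 and the whole directed matrix is divided by its maximum,
giving relative rates in (0, 1] whose maximum is exactly 1.

d is floored at 1e-6 before inversion, so an undifferentiated (e.g.
identical) pair saturates at the maximal relative rate rather than dividing
by zero.

Orientation convention: the entry ``m[i, j]`` is the relative migration from
i INTO j and is computed from the differentiation of j (the recipient) from
the i/j pool.  Asymmetry between the two directions of a pair is assessed by
non-overlap of bootstrap-over-loci percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, allele_counts

__all__ = ["MigrationNetwork", "relative_migration", "asymmetry_table"]

_D_FLOOR = 1e-6


@dataclass
class MigrationNetwork:
    """Directed relative migration matrix with optional bootstrap intervals.

    ``m.loc[i, j]`` is the relative rate from population ``i`` into ``j``;
    the diagonal is NaN.  ``ci_low``/``ci_high`` are present when the network
    was bootstrapped (``n_boot > 0``).
    """

    populations: list[str]
    m: pd.DataFrame
    n_boot: int = 0
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None

    def edge_list(self) -> pd.DataFrame:
        """Tidy directed edge list (source, target, rate[, ci_low, ci_high])."""
        rows = []
        for a in self.populations:
            for b in self.populations:
                if a == b:
                    continue
                row = {"source": a, "target": b, "rate": self.m.loc[a, b]}
                if self.ci_low is not None:
                    row["ci_low"] = self.ci_low.loc[a, b]
                    row["ci_high"] = self.ci_high.loc[a, b]
                rows.append(row)
        return pd.DataFrame(rows)


def _gst_pair_sums(pa: np.ndarray, pb: np.ndarray) -> float:
    """Nei G_ST between two frequency vectors, multi-locus via sums."""
    ok = ~(np.isnan(pa) | np.isnan(pb))
    if not ok.any():
        return np.nan
    pa, pb = pa[ok], pb[ok]
    hs = 0.5 * (2 * pa * (1 - pa) + 2 * pb * (1 - pb))
    pbar = 0.5 * (pa + pb)
    ht = 2 * pbar * (1 - pbar)
    ht_sum = ht.sum()
    if ht_sum == 0:
        return 0.0
    return float((ht_sum - hs.sum()) / ht_sum)


def _directed_matrix(freqs: np.ndarray) -> np.ndarray:
    """Unnormalized directed Nm matrix from per-population frequencies."""
    r = freqs.shape[0]
    nm = np.full((r, r), np.nan)
    for i in range(r):
        for j in range(r):
            if i == j:
                continue
            pool = 0.5 * (freqs[i] + freqs[j])
            d_recipient = _gst_pair_sums(freqs[j], pool)
            if np.isnan(d_recipient):
                continue
            d = max(d_recipient, _D_FLOOR)
            nm[i, j] = (1.0 / d - 1.0) / 4.0
    return nm


def _normalize(nm: np.ndarray) -> np.ndarray:
    top = np.nanmax(nm)
    if not np.isfinite(top) or top <= 0:
        # all pairs at or past saturation: flat network
        out = np.where(np.isnan(nm), np.nan, 1.0)
        return out
    return nm / top


def relative_migration(
    gm: GenotypeMatrix, n_boot: int = 0, seed: int | None = None, alpha: float = 0.05
) -> MigrationNetwork:
    """Directional relative migration network (G_ST based).

    With ``n_boot > 0``, loci are resampled with replacement, the full
    network (including its per-replicate normalization) is recomputed, and
    percentile intervals at ``alpha`` are attached.  Deterministic given
    ``seed``.
    """
    pops = gm.population_names
    if len(pops) < 2:
        raise ValueError("relative migration needs >= 2 populations")
    freqs = allele_counts(gm).frequencies()
    m = _normalize(_directed_matrix(freqs))
    net = MigrationNetwork(pops, pd.DataFrame(m, index=pops, columns=pops))

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        L = gm.n_loci
        reps = np.empty((n_boot, len(pops), len(pops)))
        for b in range(n_boot):
            idx = rng.integers(0, L, size=L)
            rep = _normalize(_directed_matrix(freqs[:, idx]))
            np.fill_diagonal(rep, 0.0)  # placeholder; diagonal reset below
            reps[b] = rep
        lo = np.nanpercentile(reps, 100 * alpha / 2, axis=0)
        hi = np.nanpercentile(reps, 100 * (1 - alpha / 2), axis=0)
        np.fill_diagonal(lo, np.nan)
        np.fill_diagonal(hi, np.nan)
        net.n_boot = n_boot
        net.ci_low = pd.DataFrame(lo, index=pops, columns=pops)
        net.ci_high = pd.DataFrame(hi, index=pops, columns=pops)
    return net


def asymmetry_table(network: MigrationNetwork) -> pd.DataFrame:
    """Per unordered pair: both directed rates and the asymmetry verdict.

    Asymmetry is significant when the bootstrap intervals of the two
    directions do not overlap; the table's ``attrs['fraction_significant']``
    carries the fraction of significantly asymmetric pairs.  Raises if the
    network has no bootstrap intervals.
    """
    if network.ci_low is None:
        raise ValueError("asymmetry assessment needs a bootstrapped network")
    rows = []
    pops = network.populations
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            m_ab = network.m.loc[a, b]
            m_ba = network.m.loc[b, a]
            lo_ab, hi_ab = network.ci_low.loc[a, b], network.ci_high.loc[a, b]
            lo_ba, hi_ba = network.ci_low.loc[b, a], network.ci_high.loc[b, a]
            significant = bool(
                np.isfinite(lo_ab) and np.isfinite(lo_ba)
                and (lo_ab > hi_ba or lo_ba > hi_ab)
            )
            if not significant:
                direction = "none"
            elif m_ab > m_ba:
                direction = f"{a}->{b}"
            else:
                direction = f"{b}->{a}"
            rows.append(
                {
                    "pop_a": a,
                    "pop_b": b,
                    "m_ab": m_ab,
                    "m_ba": m_ba,
                    "significant": significant,
                    "direction": direction,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["fraction_significant"] = (
        float(table["significant"].mean()) if len(table) else np.nan
    )
    return table
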