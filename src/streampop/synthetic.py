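"""Balding–Nichols generator of ddRAD-like hierarchical SNP datasets.

Emulates the statistical structure of multi-stream SNP surveys: strong
divergence between streams, weak divergence between sites within a stream,
moderate missingness.  Per locus an ancestral frequency ``p0`` is drawn
uniformly; each stream draws its frequency from a Beta distribution with
mean ``p0`` and variance ``F_stream * p0 * (1 - p0)`` (the Balding–Nichols
parameterization), and each site within a stream repeats the construction
around the stream frequency with parameter ``F_site``.  Genotypes are
Binomial(2, p_site) — Hardy–Weinberg within sites — and missingness is
applied completely at random.

The closed-form F parameters make estimator-recovery tests possible: the
expected Weir–Cockerham theta between two sites of one stream is a known
function of ``F_site`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_stream_dataset", "preset_study_like"]


@dataclass
class SyntheticSpec:
    n_streams: int = 4
    sites_per_stream: int = 4
    individuals_per_site: int = 10
    n_loci: int = 1500
    F_stream: float = 0.3
    F_site: float = 0.02
    missing_rate: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.F_site <= self.F_stream < 1.0:
            raise ValueError("need 0 <= F_site <= F_stream < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Latent frequencies behind a generated dataset."""

    spec: SyntheticSpec
    p_ancestral: np.ndarray            # (n_loci,)
    p_stream: np.ndarray               # (n_streams, n_loci)
    p_site: np.ndarray                 # (n_streams, sites_per_stream, n_loci)
    site_labels: list[str] = field(default_factory=list)


def _balding_nichols(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Draw frequencies with mean ``p`` and variance ``F p (1-p)``.

    ``F = 0`` returns an exact copy; fixed frequencies (0 or 1) stay fixed.
    """
    if F == 0:
        return p.copy()
    scale = (1.0 - F) / F
    out = p.copy()
    interior = (p > 0) & (p < 1)
    pi = p[interior]
    out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def generate_stream_dataset(spec: SyntheticSpec) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Generate one hierarchical dataset; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_freq_range
    L = spec.n_loci
    p0 = rng.uniform(lo, hi, size=L)

    p_stream = np.empty((spec.n_streams, L))
    p_site = np.empty((spec.n_streams, spec.sites_per_stream, L))
    for s in range(spec.n_streams):
        p_stream[s] = _balding_nichols(p0, spec.F_stream, rng)
        for t in range(spec.sites_per_stream):
            p_site[s, t] = _balding_nichols(p_stream[s], spec.F_site, rng)

    ids, pops, blocks, site_labels = [], [], [], []
    for s in range(spec.n_streams):
        for t in range(spec.sites_per_stream):
            label = f"st{s + 1}_s{t + 1}"
            site_labels.append(label)
            g = rng.binomial(2, p_site[s, t], size=(spec.individuals_per_site, L))
            blocks.append(g.astype(np.int8))
            for k in range(spec.individuals_per_site):
                ids.append(f"{label}_i{k + 1}")
                pops.append(label)
    geno = np.concatenate(blocks, axis=0)
    if spec.missing_rate > 0:
        mask = rng.random(geno.shape) < spec.missing_rate
        geno[mask] = MISSING
    loci = [f"L{j}" for j in range(L)]
    gm = GenotypeMatrix(ids, pops, geno, loci)
    return gm, SyntheticTruth(spec, p0, p_stream, p_site, site_labels)


def preset_study_like(seed: int | None = None) -> GenotypeMatrix:
    """Fixed study-shaped fixture: 4 streams x 4 sites x 10 individuals.

    1500 loci, F_stream = 0.3, F_site = 0.02, 10% missingness — enough
    structure to exercise filtering, pooling, every estimator and the
    barrier-comparison layout end to end.
    """
    spec = SyntheticSpec(
        n_streams=4,
        sites_per_stream=4,
        individuals_per_site=10,
        n_loci=1500,
        F_stream=0.3,
        F_site=0.02,
        missing_rate=0.1,
        seed=seed,
    )
    gm, _ = generate_stream_dataset(spec)
    return gm
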