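"""Forward-time simulator of a linear stream of demes with barriers.

The model is a discrete-generation, individual-based stepping-stone
metapopulation on a line of demes ordered from the most upstream (index 0)
to the most downstream (index ``n_demes - 1``).  Each generation:

1. **extinction** — local extinction pressure strikes the adults before
   breeding.  In the default ``proportion`` mode each deme independently
   loses a Binomial(n, e) share of its adults (a per-generation
   extinction-mortality event: demes stay occupied, their effective size is
   cut).  In ``patch`` mode each deme is instead emptied outright with
   probability ``e``; an emptied deme is recolonized only by dispersing
   offspring, which can arrive in the same generation — the classic
   extinction–recolonization cycle.  Patch-mode draws are conditioned on
   metapopulation persistence: if a draw would empty every occupied deme,
   one uniformly chosen occupied deme is spared, since a globally extinct
   run has no further dynamics to analyze.
2. **reproduction** — every occupied deme produces exactly ``K`` offspring.
   Under random mating each offspring's two parents are drawn uniformly with
   replacement; hermaphrodites self with probability ``s`` (both gametes
   from one parent) and otherwise take two distinct parents.  Each
   transmitted allele flips with probability ``mu`` (two-allele mutation).
3. **dispersal** — each offspring moves to an adjacent deme according to the
   current dispersal matrix (barrier-adjusted once the barrier is in place).
4. **regulation** — demes above ``K`` are down-sampled uniformly to ``K``.

Snapshots of the full census are taken every ``snapshot_every`` generations
(including generation 0) and can be exported as FSTAT files.  The whole run
is a deterministic function of the seed.

Loci are unlinked biallelic markers stored as reference dosage.  Initial
allele frequencies are drawn once per locus (shared by all demes — a common
ancestral pool) from a uniform interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import GenotypeMatrix, EmptyResultError, write_fstat

__all__ = [
    "DispersalMatrix",
    "BarrierSpec",
    "SimulationConfig",
    "Snapshot",
    "build_dispersal",
    "apply_barrier",
    "run_simulation",
    "sample_for_analysis",
]

#: named presets: (downstream rate, upstream rate) per generation
DISPERSAL_PRESETS = {
    "asymmetric15": (0.15, 0.05),
    "symmetric10": (0.10, 0.10),
}


@dataclass
class DispersalMatrix:
    """Adjacent-deme per-generation movement probabilities.

    ``matrix[i, j]`` is the probability that an offspring born in deme ``i``
    settles in deme ``j``; rows sum to one (the diagonal is the probability
    of staying).  Movement is restricted to adjacent demes in stream order;
    at the ends the blocked direction's mass is added to staying.
    """

    matrix: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("dispersal matrix must be square")
        if (m < 0).any():
            raise ValueError("dispersal probabilities must be >= 0")
        off = m.copy()
        np.fill_diagonal(off, 0.0)
        band = np.abs(np.subtract.outer(np.arange(m.shape[0]), np.arange(m.shape[0]))) == 1
        if (off[~band] != 0).any():
            raise ValueError("movement only allowed between adjacent demes")
        if (off.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("per-row emigration exceeds 1")
        self.matrix = m

    @property
    def n_demes(self) -> int:
        return self.matrix.shape[0]


def build_dispersal(
    preset: str | None = "asymmetric15",
    n_demes: int = 6,
    downstream: float | None = None,
    upstream: float | None = None,
) -> DispersalMatrix:
    """Build an adjacent-deme dispersal matrix from a preset or explicit rates.

    ``asymmetric15`` is flow-biased 3:1 (downstream 0.15, upstream 0.05);
    ``symmetric10`` is 0.10 both ways.  Explicit ``downstream``/``upstream``
    override the preset.  Deme 0 is the most upstream.
    """
    if downstream is None or upstream is None:
        if preset not in DISPERSAL_PRESETS:
            raise KeyError(f"unknown dispersal preset {preset!r}")
        d, u = DISPERSAL_PRESETS[preset]
        downstream = d if downstream is None else downstream
        upstream = u if upstream is None else upstream
        name = preset
    else:
        name = preset or "custom"
    if downstream + upstream > 1:
        raise ValueError("downstream + upstream emigration exceeds 1")
    m = np.zeros((n_demes, n_demes))
    for i in range(n_demes):
        if i + 1 < n_demes:
            m[i, i + 1] = downstream
        if i - 1 >= 0:
            m[i, i - 1] = upstream
        m[i, i] = 1.0 - m[i].sum()
    return DispersalMatrix(m, name=name)


@dataclass
class BarrierSpec:
    """A barrier on the edge between demes ``edge`` and ``edge + 1``.

    Models: ``complete`` blocks both directions; ``upstream_block`` blocks
    only upstream movement (downstream unchanged); ``upstream_block_reduced_down``
    blocks upstream movement and sets the downstream crossing to the absolute
    per-generation probability ``residual_down``.  The barrier takes effect
    after generation ``t_b``.
    """

    edge: int = 2
    model: str = "complete"
    residual_down: float = 0.0
    t_b: int = 100

    MODELS = ("complete", "upstream_block", "upstream_block_reduced_down")

    def __post_init__(self) -> None:
        if self.model not in self.MODELS:
            raise ValueError(f"unknown barrier model {self.model!r}")
        if not 0.0 <= self.residual_down <= 1.0:
            raise ValueError("residual_down must be in [0, 1]")
        if self.t_b < 0:
            raise ValueError("t_b must be >= 0")


def apply_barrier(d: DispersalMatrix, b: BarrierSpec) -> DispersalMatrix:
    """Return a new dispersal matrix with the barrier imposed on its edge.

    Removed (or added) cross-edge mass is absorbed by the stay probability,
    so rows still sum to one.
    """
    u = b.edge
    if not 0 <= u < d.n_demes - 1:
        raise ValueError(f"barrier edge {u} outside 0..{d.n_demes - 2}")
    m = d.matrix.copy()
    if b.model == "complete":
        m[u, u + 1] = 0.0
        m[u + 1, u] = 0.0
    elif b.model == "upstream_block":
        m[u + 1, u] = 0.0
    else:  # upstream_block_reduced_down
        m[u + 1, u] = 0.0
        m[u, u + 1] = b.residual_down
    for i in (u, u + 1):
        off = m[i].sum() - m[i, i]
        m[i, i] = 1.0 - off
    return DispersalMatrix(m, name=f"{d.name}+{b.model}")


@dataclass
class SimulationConfig:
    """Parameters of one forward-time run.  See the module docstring.

    ``burn_in`` generations are simulated without the barrier; the barrier
    (if any) acts from generation ``barrier.t_b + 1`` onward, which defaults
    to the end of the burn-in.
    """

    n_demes: int = 6
    K: int = 100
    mating: str = "random_mating"  # or "hermaphrodite"
    s: float = 0.0                 # selfing rate (hermaphrodite only)
    e: float = 0.0                 # per-deme per-generation extinction
    extinction_mode: str = "proportion"  # "proportion" or "patch"
    n_loci: int = 500
    mu: float = 1e-4
    init_freq: tuple[float, float] = (0.1, 0.9)
    generations: int = 250
    burn_in: int = 100
    snapshot_every: int = 5
    dispersal: DispersalMatrix | None = None
    barrier: BarrierSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mating not in ("random_mating", "hermaphrodite"):
            raise ValueError(f"unknown mating system {self.mating!r}")
        if self.extinction_mode not in ("proportion", "patch"):
            raise ValueError(f"unknown extinction_mode {self.extinction_mode!r}")
        for name in ("s", "e", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.burn_in > self.generations:
            raise ValueError("burn_in must not exceed generations")
        if self.dispersal is None:
            self.dispersal = build_dispersal("asymmetric15", self.n_demes)
        if self.dispersal.n_demes != self.n_demes:
            raise ValueError("dispersal matrix size does not match n_demes")
        if self.barrier is not None and self.barrier.t_b is None:
            self.barrier = replace(self.barrier, t_b=self.burn_in)

    def to_metadata(self) -> dict:
        return {
            "n_demes": self.n_demes,
            "K": self.K,
            "mating": self.mating,
            "s": self.s,
            "e": self.e,
            "extinction_mode": self.extinction_mode,
            "n_loci": self.n_loci,
            "mu": self.mu,
            "init_freq": list(self.init_freq),
            "generations": self.generations,
            "burn_in": self.burn_in,
            "snapshot_every": self.snapshot_every,
            "dispersal": self.dispersal.name,
            "barrier": None
            if self.barrier is None
            else {
                "edge": self.barrier.edge,
                "model": self.barrier.model,
                "residual_down": self.barrier.residual_down,
                "t_b": self.barrier.t_b,
            },
            "seed": self.seed,
            "life_cycle": "extinction->breed->disperse->regulate",
        }


@dataclass
class Snapshot:
    """Full census at one generation: per-deme dosage arrays."""

    generation: int
    demes: list[np.ndarray] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [d.shape[0] for d in self.demes]

    def to_genotype_matrix(self, prefix: str = "deme") -> GenotypeMatrix:
        """Census as a GenotypeMatrix; empty demes are skipped."""
        ids, pops, blocks = [], [], []
        for i, deme in enumerate(self.demes):
            if deme.shape[0] == 0:
                continue
            label = f"{prefix}{i}"
            for k in range(deme.shape[0]):
                ids.append(f"{label}_g{self.generation}_{k}")
                pops.append(label)
            blocks.append(deme)
        if not blocks:
            raise EmptyResultError(f"generation {self.generation}: all demes empty")
        geno = np.concatenate(blocks, axis=0)
        loci = [f"L{j}" for j in range(geno.shape[1])]
        return GenotypeMatrix(ids, pops, geno, loci)


def _breed(deme: np.ndarray, K: int, mating: str, s: float, mu: float,
           rng: np.random.Generator) -> np.ndarray:
    """K offspring dosages from one deme's adults."""
    n, L = deme.shape
    if mating == "random_mating":
        i1 = rng.integers(0, n, K)
        i2 = rng.integers(0, n, K)
    else:
        i1 = rng.integers(0, n, K)
        if n == 1:
            i2 = i1.copy()
        else:
            selfing = rng.random(K) < s
            i2 = rng.integers(0, n - 1, K)
            i2[i2 >= i1] += 1
            i2[selfing] = i1[selfing]
    half1 = deme[i1].astype(np.float32) * 0.5
    half2 = deme[i2].astype(np.float32) * 0.5
    g1 = rng.random((K, L), dtype=np.float32) < half1
    g2 = rng.random((K, L), dtype=np.float32) < half2
    if mu > 0:
        for g in (g1, g2):
            n_mut = rng.binomial(K * L, mu)
            if n_mut:
                pos = rng.integers(0, K * L, n_mut)
                flat = g.reshape(-1)
                flat[pos] = ~flat[pos]
    return (g1.astype(np.int8) + g2.astype(np.int8))


def run_simulation(
    config: SimulationConfig, out_dir=None, initial_demes=None
) -> list[Snapshot]:
    """Run the full life cycle and return census snapshots.

    Snapshots are taken at generation 0 and every ``snapshot_every``
    generations thereafter.  If ``out_dir`` is given, each snapshot is also
    written as ``gen<G>.dat`` (FSTAT) together with a ``run.json`` metadata
    file recording the configuration, life-cycle order and seed.
    ``initial_demes`` (a list of per-deme dosage arrays) overrides the
    default common-ancestral-pool initialization, e.g. to place a marker
    allele on one side of a barrier.
    """
    rng = np.random.default_rng(config.seed)
    n_demes, K, L = config.n_demes, config.K, config.n_loci

    if initial_demes is not None:
        if len(initial_demes) != n_demes:
            raise ValueError("initial_demes must match n_demes")
        demes = [np.asarray(d, dtype=np.int8).reshape(-1, L).copy() for d in initial_demes]
    else:
        lo, hi = config.init_freq
        p0 = rng.uniform(lo, hi, size=L)
        demes = [
            (rng.random((K, L)) < p0).astype(np.int8)
            + (rng.random((K, L)) < p0).astype(np.int8)
            for _ in range(n_demes)
        ]

    base = config.dispersal
    with_barrier = base if config.barrier is None else apply_barrier(base, config.barrier)
    t_b = config.barrier.t_b if config.barrier is not None else config.generations + 1

    snapshots = [Snapshot(0, [d.copy() for d in demes])]
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "run.json").write_text(json.dumps(config.to_metadata(), indent=2))
        _write_snapshot(snapshots[0], out_path)

    for g in range(1, config.generations + 1):
        disp = with_barrier if g > t_b else base

        # 1. extinction pressure on adults (before breeding)
        if config.e > 0:
            if config.extinction_mode == "proportion":
                for i in range(n_demes):
                    d = demes[i]
                    if d.shape[0]:
                        demes[i] = d[rng.random(d.shape[0]) >= config.e]
            else:  # patch mode, conditioned on metapopulation persistence
                occupied = [i for i, d in enumerate(demes) if d.shape[0] > 0]
                extinct = rng.random(n_demes) < config.e
                if occupied and all(extinct[i] for i in occupied):
                    extinct[occupied[rng.integers(0, len(occupied))]] = False
                for i in range(n_demes):
                    if extinct[i]:
                        demes[i] = demes[i][:0]

        # 2. reproduction: each occupied deme produces K offspring
        broods = [
            _breed(d, K, config.mating, config.s, config.mu, rng)
            if d.shape[0] > 0 else d[:0]
            for d in demes
        ]

        # 3. dispersal of offspring between adjacent demes
        arrivals: list[list[np.ndarray]] = [[] for _ in range(n_demes)]
        for i, brood in enumerate(broods):
            if brood.shape[0] == 0:
                continue
            down = disp.matrix[i, i + 1] if i + 1 < n_demes else 0.0
            up = disp.matrix[i, i - 1] if i - 1 >= 0 else 0.0
            u = rng.random(brood.shape[0])
            go_down = u < down
            go_up = (u >= down) & (u < down + up)
            stay = ~(go_down | go_up)
            if go_down.any():
                arrivals[i + 1].append(brood[go_down])
            if go_up.any():
                arrivals[i - 1].append(brood[go_up])
            arrivals[i].append(brood[stay])

        # 4. regulation to K
        new_demes = []
        for i in range(n_demes):
            if arrivals[i]:
                pool = np.concatenate(arrivals[i], axis=0)
            else:
                pool = demes[i][:0]
            if pool.shape[0] > K:
                pool = pool[rng.permutation(pool.shape[0])[:K]]
            new_demes.append(pool)
        demes = new_demes

        if all(d.shape[0] == 0 for d in demes):
            raise EmptyResultError(
                f"metapopulation extinct at generation {g} "
                f"(e={config.e}); no further dynamics to simulate"
            )

        if g % config.snapshot_every == 0:
            snap = Snapshot(g, [d.copy() for d in demes])
            snapshots.append(snap)
            if out_path is not None:
                _write_snapshot(snap, out_path)

    return snapshots


def _write_snapshot(snap: Snapshot, out_path: Path) -> None:
    try:
        gm = snap.to_genotype_matrix()
    except EmptyResultError:
        return
    write_fstat(gm, out_path / f"gen{snap.generation}.dat")


def sample_for_analysis(
    snapshot: Snapshot,
    n: int = 10,
    exclude_edges: bool = True,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Random sample of ``n`` individuals per analyzable deme.

    Edge demes (first and last) are dropped when ``exclude_edges`` — they
    only exist to avoid boundary artefacts — and demes with fewer than ``n``
    individuals are excluded entirely.  Sampling is without replacement and
    deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_demes = len(snapshot.demes)
    keep = range(1, n_demes - 1) if exclude_edges else range(n_demes)
    ids, pops, blocks = [], [], []
    for i in keep:
        deme = snapshot.demes[i]
        if deme.shape[0] < n:
            continue
        idx = rng.choice(deme.shape[0], size=n, replace=False)
        label = f"deme{i}"
        for k in idx:
            ids.append(f"{label}_g{snapshot.generation}_{k}")
            pops.append(label)
        blocks.append(deme[idx])
    if not blocks:
        raise EmptyResultError(
            f"generation {snapshot.generation}: no deme has >= {n} individuals"
        )
    geno = np.concatenate(blocks, axis=0)
    loci = [f"L{j}" for j in range(geno.shape[1])]
    return GenotypeMatrix(ids, pops, geno, loci)
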