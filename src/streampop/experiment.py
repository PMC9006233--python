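"""Barrier-effect detection experiments over simulated parameter grids.

Ties the simulator to the statistic stack: run a grid of life-history /
barrier scenarios, compute per-snapshot pairwise differentiation with
bootstrap intervals, apply the barrier-detection rule, evaluate directional
migration networks at fixed time points, and build the reference-versus-
cross-barrier comparison tables that feed downstream (external) model fits.

The detection rule operationalizes "consistently higher differentiation
across the barrier": at a post-barrier snapshot the effect counts as
detected when (a) every cross-barrier pair is significant (bootstrap lower
bound above zero), (b) the smallest cross-barrier estimate exceeds the
largest reference estimate, and (c) both conditions persist for the next
``persistence`` consecutive snapshots.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EmptyResultError
from .migration import MigrationNetwork, relative_migration
from .simulate import (
    BarrierSpec,
    SimulationConfig,
    Snapshot,
    build_dispersal,
    run_simulation,
    sample_for_analysis,
)
from .stats import FstResult, allelic_richness, bootstrap_fst_ci, diversity_stats

__all__ = [
    "BarrierLayout",
    "DetectionResult",
    "GridSpec",
    "fst_series_from_run",
    "detect_barrier_effect",
    "divmigrate_timepoints",
    "barrier_vs_reference",
    "ibd_analysis",
    "run_grid",
    "replicate_seed",
]


@dataclass(frozen=True)
class BarrierLayout:
    """Which population pairs straddle the barrier and which are references.

    The layout is explicit input — never inferred from labels.  For the
    standard six-deme run with the barrier on edge 2 (between demes 2 and 3)
    and the interior demes analyzed, use :meth:`from_sides` with upstream
    ``deme1, deme2`` and downstream ``deme3, deme4``.
    """

    upstream: tuple[str, ...]
    downstream: tuple[str, ...]

    @classmethod
    def from_sides(cls, upstream, downstream) -> "BarrierLayout":
        return cls(tuple(upstream), tuple(downstream))

    @classmethod
    def standard_six_deme(cls, barrier_edge: int = 2, n_demes: int = 6) -> "BarrierLayout":
        interior = [f"deme{i}" for i in range(1, n_demes - 1)]
        up = tuple(d for d in interior if int(d[4:]) <= barrier_edge)
        down = tuple(d for d in interior if int(d[4:]) > barrier_edge)
        return cls(up, down)

    @property
    def populations(self) -> tuple[str, ...]:
        return self.upstream + self.downstream

    @property
    def cross_pairs(self) -> list[tuple[str, str]]:
        return [(u, d) for u in self.upstream for d in self.downstream]

    @property
    def reference_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for side in (self.upstream, self.downstream):
            pairs.extend(
                (side[i], side[j]) for i in range(len(side)) for j in range(i + 1, len(side))
            )
        return pairs


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def fst_series_from_run(
    snapshots: list[Snapshot],
    layout: BarrierLayout,
    n_boot: int = 1000,
    sample_n: int = 10,
    seed: int | None = None,
    start_generation: int = 0,
) -> dict[int, dict[tuple[str, str], FstResult]]:
    """Per-snapshot pairwise theta with bootstrap CIs for the layout's pairs.

    Each snapshot is down-sampled to ``sample_n`` individuals per deme (edge
    demes excluded, small demes dropped); pairs whose populations are absent
    at a time point are simply missing from that snapshot's dict.
    """
    rng = np.random.default_rng(seed)
    series: dict[int, dict[tuple[str, str], FstResult]] = {}
    all_pairs = [
        _pair_key(*p) for p in (layout.cross_pairs + layout.reference_pairs)
    ]
    for snap in snapshots:
        if snap.generation < start_generation:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            gm = sample_for_analysis(snap, n=sample_n, seed=sub_seed)
        except EmptyResultError:
            series[snap.generation] = {}
            continue
        present = set(gm.population_names)
        out: dict[tuple[str, str], FstResult] = {}
        for a, b in all_pairs:
            if a in present and b in present:
                out[(a, b)] = bootstrap_fst_ci(
                    gm, pair=[a, b], n_boot=n_boot,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
        series[snap.generation] = out
    return series


@dataclass
class DetectionResult:
    detected: bool
    detection_generation: int | None   # generations after the barrier
    trace: pd.DataFrame                # per-snapshot criterion trace

    def __bool__(self) -> bool:  # convenience: truthy when detected
        return self.detected


def detect_barrier_effect(
    series: dict[int, dict[tuple[str, str], FstResult]],
    layout: BarrierLayout,
    t_b: int,
    persistence: int = 2,
) -> DetectionResult:
    """First post-barrier snapshot with a persistent cross-barrier excess.

    Criterion per snapshot: every cross-barrier pair present and significant,
    and the minimum cross-barrier estimate above the maximum reference
    estimate (at least one reference pair must be present).  Detection
    requires the criterion to also hold at the next ``persistence``
    snapshots; ``detection_generation`` is the first qualifying snapshot
    minus ``t_b``.
    """
    cross = {_pair_key(*p) for p in layout.cross_pairs}
    refs = {_pair_key(*p) for p in layout.reference_pairs}
    gens = sorted(g for g in series if g > t_b)
    rows = []
    ok = []
    for g in gens:
        res = series[g]
        cross_here = [res[p] for p in cross if p in res]
        ref_here = [res[p] for p in refs if p in res]
        complete = len(cross_here) == len(cross) and len(ref_here) >= 1
        all_sig = complete and all(r.significant for r in cross_here)
        excess = complete and (
            min(r.estimate for r in cross_here) > max(r.estimate for r in ref_here)
        )
        passed = bool(all_sig and excess)
        ok.append(passed)
        rows.append(
            {
                "generation": g,
                "n_cross": len(cross_here),
                "n_reference": len(ref_here),
                "all_cross_significant": bool(all_sig),
                "cross_exceeds_reference": bool(excess),
                "criterion": passed,
            }
        )
    trace = pd.DataFrame(rows)
    for i, g in enumerate(gens):
        window = ok[i : i + persistence + 1]
        if len(window) < persistence + 1:
            break
        if all(window):
            return DetectionResult(True, g - t_b, trace)
    return DetectionResult(False, None, trace)


DEFAULT_TIMEPOINTS = (5, 50, 95, 110, 150, 200, 250)


def divmigrate_timepoints(
    snapshots: list[Snapshot],
    layout: BarrierLayout,
    generations=DEFAULT_TIMEPOINTS,
    t_b: int = 100,
    sample_n: int = 10,
    n_boot: int = 0,
    seed: int | None = None,
) -> tuple[dict[int, MigrationNetwork], pd.DataFrame]:
    """Relative migration networks at fixed time points + reduction flags.

    For each post-barrier time point, a reduction is flagged when every
    evaluable directed cross-barrier edge falls below the minimum rate the
    same edge showed at the pre-barrier time points.  Edges lacking either a
    pre-barrier baseline or a current value (excluded demes) are skipped; a
    time point with no evaluable cross edge is flagged ``NaN``.
    """
    by_gen = {s.generation: s for s in snapshots}
    missing = [g for g in generations if g not in by_gen]
    if missing:
        raise KeyError(
            f"snapshots missing for generations {missing}; "
            f"available: {sorted(by_gen)}"
        )
    rng = np.random.default_rng(seed)
    networks: dict[int, MigrationNetwork] = {}
    for g in generations:
        try:
            gm = sample_for_analysis(
                by_gen[g], n=sample_n, seed=int(rng.integers(0, 2**31 - 1))
            )
        except EmptyResultError:
            continue
        if len(gm.population_names) < 2:
            continue  # too few demes above the sampling floor at this time point
        networks[g] = relative_migration(
            gm, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1))
        )

    cross_edges = [(a, b) for a, b in layout.cross_pairs] + [
        (b, a) for a, b in layout.cross_pairs
    ]
    pre = [g for g in generations if g <= t_b and g in networks]
    post = [g for g in generations if g > t_b]

    def edge_rate(net: MigrationNetwork, a: str, b: str) -> float:
        if a in net.m.index and b in net.m.columns:
            return float(net.m.loc[a, b])
        return np.nan

    baseline = {
        e: np.nanmin([edge_rate(networks[g], *e) for g in pre]) if pre else np.nan
        for e in cross_edges
    }
    rows = []
    for g in post:
        if g not in networks:
            rows.append({"generation": g, "n_edges": 0, "reduction_detected": np.nan})
            continue
        verdicts = []
        for e in cross_edges:
            now = edge_rate(networks[g], *e)
            base = baseline[e]
            if np.isnan(now) or np.isnan(base):
                continue
            verdicts.append(now < base)
        rows.append(
            {
                "generation": g,
                "n_edges": len(verdicts),
                "reduction_detected": bool(verdicts and all(verdicts))
                if verdicts else np.nan,
            }
        )
    return networks, pd.DataFrame(rows)


def barrier_vs_reference(fst_matrix: pd.DataFrame, layout: BarrierLayout) -> pd.DataFrame:
    """Mean differentiation among reference pairs vs across the barrier.

    Returns a one-row table (mean_reference, mean_cross, difference) plus a
    per-pair long table in ``attrs['pairs']``.  A side without any sampled
    pair leaves the corresponding mean NaN.
    """
    for pop in layout.populations:
        if pop not in fst_matrix.index:
            raise KeyError(f"population {pop!r} missing from F_ST matrix")
    pair_rows = []
    for kind, pairs in (("reference", layout.reference_pairs),
                        ("cross", layout.cross_pairs)):
        for a, b in pairs:
            pair_rows.append({"pair": f"{a}-{b}", "kind": kind,
                              "fst": float(fst_matrix.loc[a, b])})
    pairs_df = pd.DataFrame(pair_rows)
    ref_vals = pairs_df.loc[pairs_df["kind"] == "reference", "fst"]
    cross_vals = pairs_df.loc[pairs_df["kind"] == "cross", "fst"]
    mean_ref = float(ref_vals.mean()) if len(ref_vals) else np.nan
    mean_cross = float(cross_vals.mean()) if len(cross_vals) else np.nan
    out = pd.DataFrame(
        [{
            "mean_reference": mean_ref,
            "mean_cross": mean_cross,
            "difference": mean_cross - mean_ref,
        }]
    )
    out.attrs["pairs"] = pairs_df
    return out


def ibd_analysis(
    fst_matrix: pd.DataFrame,
    distance_matrices: dict[str, pd.DataFrame],
    n_perm: int = 9_999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel isolation-by-distance tests against each geographic distance."""
    from .stats import mantel_test

    rng = np.random.default_rng(seed)
    rows = []
    for name, dist in distance_matrices.items():
        r, p = mantel_test(
            fst_matrix, dist, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        rows.append({"distance": name, "mantel_r": r, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter-grid runner


@dataclass
class GridSpec:
    """Cartesian product of scenario axes, with deterministic replicate seeds."""

    K: tuple[int, ...] = (100, 1000)
    mating: tuple[tuple[str, float], ...] = (("random_mating", 0.0),)
    e: tuple[float, ...] = (0.0, 0.6)
    dispersal: tuple[str, ...] = ("asymmetric15",)
    barrier: tuple[tuple[str, float], ...] = (("complete", 0.0),)
    n_replicates: int = 5
    base_seed: int = 0
    n_loci: int = 500
    generations: int = 250
    burn_in: int = 100
    snapshot_every: int = 5
    n_demes: int = 6
    barrier_edge: int = 2

    def cells(self):
        for K, (mating, s), e, disp, (model, residual) in itertools.product(
            self.K, self.mating, self.e, self.dispersal, self.barrier
        ):
            yield {
                "K": K, "mating": mating, "s": s, "e": e,
                "dispersal": disp, "barrier_model": model,
                "residual_down": residual,
            }


def replicate_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence((base_seed, cell_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def config_for_cell(grid: GridSpec, cell: dict, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_demes=grid.n_demes,
        K=cell["K"],
        mating=cell["mating"],
        s=cell["s"],
        e=cell["e"],
        n_loci=grid.n_loci,
        generations=grid.generations,
        burn_in=grid.burn_in,
        snapshot_every=grid.snapshot_every,
        dispersal=build_dispersal(cell["dispersal"], grid.n_demes),
        barrier=BarrierSpec(
            edge=grid.barrier_edge,
            model=cell["barrier_model"],
            residual_down=cell["residual_down"],
            t_b=grid.burn_in,
        ),
        seed=seed,
    )


def run_grid(
    grid: GridSpec,
    out_dir=None,
    n_boot: int = 0,
    sample_n: int = 10,
) -> pd.DataFrame:
    """Run every cell x replicate and emit a long-format statistics table.

    Per snapshot: pairwise theta (with CIs when ``n_boot > 0``) for every
    analyzed pair, plus per-population H_O and rarefied allelic richness.
    One row per (cell, replicate, generation, statistic, pair-or-population);
    every row carries the replicate's seed.  If ``out_dir`` is given, each
    cell is written to ``cell<i>.csv`` and already-written cells are skipped
    on re-run (resumability); failures are recorded and the grid continues.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    layout = BarrierLayout.standard_six_deme(grid.barrier_edge, grid.n_demes)
    frames = []
    for ci, cell in enumerate(grid.cells()):
        cell_file = out_path / f"cell{ci}.csv" if out_path is not None else None
        if cell_file is not None and cell_file.exists():
            frames.append(pd.read_csv(cell_file))
            continue
        rows = []
        for rep in range(grid.n_replicates):
            seed = replicate_seed(grid.base_seed, ci, rep)
            try:
                rows.extend(
                    _cell_replicate_rows(grid, cell, layout, rep, seed, n_boot, sample_n)
                )
            except Exception as exc:  # cell failure recorded, grid continues
                rows.append(
                    {**cell, "replicate": rep, "seed": seed, "generation": -1,
                     "statistic": "error", "unit": "", "value": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "note": str(exc)}
                )
        frame = pd.DataFrame(rows)
        if cell_file is not None:
            frame.to_csv(cell_file, index=False)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _cell_replicate_rows(grid, cell, layout, rep, seed, n_boot, sample_n):
    config = config_for_cell(grid, cell, seed)
    snapshots = run_simulation(config)
    stat_rng = np.random.default_rng(replicate_seed(grid.base_seed + 1, 0, seed % 10_000))
    rows = []
    base = {**cell, "replicate": rep, "seed": seed}
    for snap in snapshots:
        try:
            gm = sample_for_analysis(
                snap, n=sample_n, seed=int(stat_rng.integers(0, 2**31 - 1))
            )
        except EmptyResultError:
            continue
        present = gm.population_names
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                pair = (present[i], present[j])
                if n_boot > 0:
                    res = bootstrap_fst_ci(
                        gm, pair=list(pair), n_boot=n_boot,
                        seed=int(stat_rng.integers(0, 2**31 - 1)),
                    )
                    est, lo, hi = res.estimate, res.ci_low, res.ci_high
                else:
                    from .stats import wc_fst

                    est, lo, hi = wc_fst(gm, populations=list(pair)), np.nan, np.nan
                rows.append({**base, "generation": snap.generation, "statistic": "fst",
                             "unit": f"{pair[0]}-{pair[1]}", "value": est,
                             "ci_low": lo, "ci_high": hi, "note": ""})
        div = diversity_stats(gm)
        ar = allelic_richness(gm)
        for pop in present:
            rows.append({**base, "generation": snap.generation, "statistic": "ho",
                         "unit": pop, "value": float(div.ho_mean[pop]),
                         "ci_low": np.nan, "ci_high": np.nan, "note": ""})
            rows.append({**base, "generation": snap.generation, "statistic": "ar",
                         "unit": pop, "value": float(ar.mean[pop]),
                         "ci_low": np.nan, "ci_high": np.nan, "note": ""})
    return rows
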