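# streampop

Population-genomic simulation and analysis of small in-stream barriers in
linear stream networks.

Millions of small weirs and culverts fragment river networks.  Whether they
actually block gene flow for strictly aquatic invertebrates (amphipods,
snails, flatworms) is hard to judge from SNP data alone, because large
population sizes limit drift and flow-biased dispersal makes barrier effects
asymmetric.  `streampop` provides the machinery used to answer that
question with simulations and genotype statistics:

* a forward-time, individual-based stepping-stone simulator of a linear
  stream (flow-biased dispersal, three barrier models, random-mating or
  hermaphroditic selfing reproduction, extinction pressure, FSTAT snapshot
  export);
* the SNP statistic stack applied to genotype matrices: observed
  heterozygosity H_O, gene diversities H_S/H_T, F_IS, Weir–Cockerham
  F_ST (overall and pairwise) with bootstrap-over-loci confidence
  intervals, Nei's G_ST, rarefied allelic richness, private alleles under
  size-matched subsampling, and Mantel isolation-by-distance tests;
* G_ST-based directional relative migration networks (divMigrate-style)
  with bootstrap asymmetry assessment;
* the barrier-effect experiment: parameter-grid runs, a persistent
  cross-barrier-excess detection rule, fixed-time-point migration-network
  evaluation, and reference-versus-cross-barrier comparison tables;
* a Balding–Nichols generator of ddRAD-like hierarchical SNP datasets for
  testing every empirical-facing step without sequencing data.

The central estimator is Weir & Cockerham's θ: per locus the allele-frequency
variance is decomposed into among-population (a), among-individual (b) and
within-individual (c) components, and the multi-locus estimate is the ratio
of sums θ = Σa / Σ(a+b+c), with significance judged by a bootstrap-over-loci
percentile interval excluding zero.  Directional migration between a pair of
populations is inferred by comparing each population with a hypothetical
migrant pool carrying their mean allele frequencies: the recipient's G_ST
from the pool d is mapped to N_m = ((1/d) − 1)/4 and the directed matrix is
normalized to a maximum of 1.

See `docs/methods.md` for the full model description, estimator definitions
and design choices.

## Worked example

Simulate six demes of capacity 100 with flow-biased dispersal, introduce a
complete barrier in the middle at generation 100, and ask when the four
analyzed populations (two per side, 10 individuals sampled each) show a
persistent cross-barrier excess in pairwise θ:

```python
import streampop as sp

cfg = sp.SimulationConfig(
    K=100, n_loci=500, generations=250, seed=42,
    barrier=sp.BarrierSpec(edge=2, model="complete", t_b=100),
)
snapshots = sp.run_simulation(cfg)
layout = sp.BarrierLayout.standard_six_deme()
series = sp.fst_series_from_run(snapshots, layout, n_boot=1000, seed=7)
det = sp.detect_barrier_effect(series, layout, t_b=100)
print(f"detected: {det.detected}, generations after barrier: {det.detection_generation}")
for pair, res in sorted(series[250].items()):
    print(f"{pair[0]}-{pair[1]}: theta={res.estimate:.3f} "
          f"CI=[{res.ci_low:.3f}, {res.ci_high:.3f}] significant={res.significant}")
```

Output:

```
detected: True, generations after barrier: 5
deme1-deme2: theta=0.004 CI=[-0.005, 0.014] significant=False
deme1-deme3: theta=0.337 CI=[0.300, 0.373] significant=True
deme1-deme4: theta=0.341 CI=[0.305, 0.379] significant=True
deme2-deme3: theta=0.324 CI=[0.289, 0.357] significant=True
deme2-deme4: theta=0.325 CI=[0.289, 0.361] significant=True
deme3-deme4: theta=0.017 CI=[0.006, 0.028] significant=True
```

At this small capacity the barrier is detected at the very first
post-barrier snapshot: after 150 generations of isolation the four
cross-barrier pairs (deme1/2 × deme3/4) have drifted to θ ≈ 0.33 with
confidence intervals far from zero, while the same-side reference pairs
remain near zero.  With capacity 2000 the same experiment takes an order of
magnitude longer to reach significance, and a barrier that blocks only
upstream movement is not detected at all — downstream dispersal alone keeps
the two sides mixed.

A command-line interface wraps the main entry points:

```sh
streampop simulate --config sim.yaml --out run_dir/   # FSTAT snapshots + metadata
streampop synth --out data.tsv --seed 1               # Balding–Nichols dataset
streampop grid --grid grid.yaml --out cells/          # parameter-grid experiment
streampop ibd --fst fst.csv --dist waterway.csv       # Mantel IBD tests
```

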