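# finescale

Fine-scale population structure and demographic inference for small,
geographically close cohorts — the kind of study where five rural valley
populations, sampled a few tens of km apart along a mountain transect,
turn out to be genetically distinguishable only with haplotype-based
methods and whole-genome data.

The package provides, as a single tested pipeline:

* **`finescale.simdata`** — a coalescent generator (msprime) for a
  five-population split model `(((G,R)GR, (U,P,B)UPB)GRUBP)` with
  uniform priors on eight effective sizes (in chromosomes) and three
  split times (in years, 29 years/generation), symmetric migration among
  the terminal populations, VCF round-trip I/O and ground-truth fixtures.
* **`finescale.coancestry`** — 1-IBS distances, classical MDS, a
  symmetric Procrustes permutation test against geography, Li-Stephens
  haplotype painting into a donor-by-recipient coancestry matrix
  (numba-compiled forward-backward), and a deterministic coancestry
  clustering surrogate (average linkage + silhouette model choice).
* **`finescale.barriers`** — a spatial model that explains normalized
  coancestry by per-group anisotropic distance metrics plus additive
  inter-group genetic barriers, with exhaustive partition search and a
  permutation significance test.
* **`finescale.diversity`** — the HR composite-LD statistic with
  MAF-matched pair selection (|ΔMAF| < 0.05), LD-decay curves, a
  sliding-window runs-of-homozygosity caller, the Kruskal-Wallis
  across-region RoH comparison, and HetR / resampling-normalized nHetR.
* **`finescale.abcinf`** — ABC inference of the demographic model with a
  learned summary regressor ("ABC-DL-lite": a small feed-forward network
  mapping classical summaries to parameters), rejection sampling, and
  posterior reports with mean, median, half-range mode, 95% CI and
  89% HDI.

Everything runs on synthetic data; no external datasets are required.

## Worked example

Simulate a structured panel (old split, no migration), paint it, cluster
the coancestry matrix and search for the best two-group barrier
partition:

```python
import numpy as np
from finescale import simdata, coancestry, barriers

params = simdata.ParameterVector(
    Ne_GRUBP=27000, Ne_GR=1600, Ne_UPB=1250, Ne_G=840, Ne_R=1680,
    Ne_U=320, Ne_P=720, Ne_B=7766,
    t_GRUBP=14500.0, t_GR=2000.0, t_UPB=1700.0, m=0.0,
)
panel = simdata.simulate_dataset(
    params, simdata.ModelConfig(sequence_length=1e6, seed=99)
)
cm = coancestry.paint_panel(panel)
clusters = coancestry.cluster_coancestry(cm, k_max=6)
best, table = barriers.search_partitions(cm, panel.coords, k=2, seed=1)
print(panel.n_sites, "sites")
print("two-group cut:", clusters.labels_by_k[2])
print("best partition:", table.iloc[0]["partition"])
```

Output:

```
2164 sites
two-group cut: [1 1 1 1 1 1 1 1 1 1 1 1 2 2 2 2 2 2 2 2 2 2 2 2 2 2 2 2 2]
best partition: B,P,U | G,R
```

The first twelve samples are the G and R individuals: the two-group cut
of the painted coancestry matrix separates {G,R} from {U,P,B}, and the
barrier-model partition search independently ranks the same split first —
the two haplotype-based routes agree on where the genetic barrier lies.

An end-to-end ABC run on a VCF (here one produced by the simulator):

```bash
finescale simulate --seed 5 --length 1000000 --out panel.vcf --map-out samples.tsv
finescale abc --observed panel.vcf --regions samples.tsv \
    --n-train 500 --n-abc 300 --accept 0.1 --length 1000000 \
    --seed 1 --out report.tsv
```

`report.tsv` has one row per demographic parameter with columns
`prior, mean, median, half_range_mode, ci_2.5, ci_97.5, hdi_low,
hdi_high` (sizes in chromosomes, times in years).

See `docs/methods.md` for the model, its assumptions, all tunable
parameters and the numerical choices.

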