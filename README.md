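# spatcorr

Quantitative spatial analysis of imaging-based transcriptomics data.
`spatcorr` takes the decoded output of an in situ sequencing or FISH-based
experiment — one record per detected RNA molecule with planar coordinates
(µm), a gene label and a decoding-quality score — and answers three
questions about the tissue:

1. **Where are the anatomical structures?**  Endocrine islets (clusters of
   hormone-producing cells marked by SST, GLUC and INS transcripts) are
   detected by density-based clustering and summarized as circles.
2. **How is each gene's expression arranged around those structures?**
   For every sufficiently abundant gene, the distances from its transcripts
   to the nearest islet boundary (or nucleus) are turned into a density
   profile by boundary-corrected kernel density estimation; profiles are
   compared pairwise by symmetric Kullback–Leibler divergence
   D(p, q) = KL(p‖q) + KL(q‖p), the genes are split into two groups by
   average-linkage clustering of the divergence matrix, and a gene's rank
   toward a group can be followed across developmental timepoints.
3. **Do transcripts of different genes attract or avoid each other?**
   Within each islet, the typed point pattern is modelled as a multitype
   Strauss process with density

   l(Z) ∝ ∏ᵢ βᵢ^{nᵢ} · ∏_{i≤j} γᵢⱼ^{sᵢⱼ}

   where nᵢ is the number of type-i transcripts, sᵢⱼ the number of
   unordered pairs of types i and j within the interaction radius
   r (default 20 µm, about twice the nuclei spacing), βᵢ the intensity and
   γᵢⱼ the pairwise interaction: γ < 1 inhibition, γ > 1 clustering,
   γ = 1 independence (Poisson).  γ is estimated per islet by maximum
   pseudolikelihood (Berman–Turner quadrature) and aggregated across
   islets as mean ± std; a fixed-count Metropolis–Hastings sampler
   simulates patterns from given parameters for validation.

The package is aimed at analysts of spatially resolved transcriptomics who
want interpretable, model-based summaries of gene–structure and gene–gene
spatial relationships rather than per-gene spatial-variability calls.

## Worked example

Everything below is reproducible; data are generated by the package's own
synthetic-tissue module, which plants islets, islet-proximal genes and
uniform background genes with known ground truth.

```python
import numpy as np
from spatcorr import (Window, MultitypeStraussModel)
from spatcorr.strauss import PointPattern

# two independent transcript types in a disc-shaped region
win = Window.circle(0.0, 0.0, 150.0)
rng = np.random.default_rng(0)
xy = np.vstack([win.sample_uniform(500, rng), win.sample_uniform(500, rng)])
types = np.array(["SST"] * 500 + ["INS"] * 500, dtype=object)

model = MultitypeStraussModel(PointPattern(xy, types, win), radius=20.0)
result = model.fit(seed=0)
print(result.summary())
```

```
Multitype Strauss process: maximum pseudolikelihood fit
  interaction radius r = 20 um, window area = 70685.8 um^2
  points: INS=500, SST=500

  pair               gamma      se    s_ij
  INS ~ INS          1.007   0.014    2114
  INS ~ SST          0.970   0.010    3994
  SST ~ SST          1.003   0.015    2083

  type              beta   se(log)
  INS           0.008593     0.156
  SST           0.008926     0.161
```

Both types were placed uniformly and independently, and the fit reports
what it should: every interaction γ is within a few standard errors of
1 (no attraction, no inhibition; averaging over replicate seeds the cross
γ is 1.00 to two decimals), and the intensities β are compatible with the
true 500 / 70 686 ≈ 0.00707 points/µm² — β and γ trade off within a single
window, which is why per-islet fits are aggregated across islets.  On real tissue the same `summary()`
read-out flags pairs with γ meaningfully above 1 (spatial co-clustering,
e.g. co-expressed stemness markers) or below 1 (mutual avoidance).

The full pipeline — QC filtering, islet detection, density profiles,
divergence matrix, gene grouping, per-islet Strauss fits and
cross-timepoint rank trajectories — runs from a YAML config:

```bash
spatcorr synth --spec tissue.yaml --out data/        # synthetic ground truth
spatcorr run --config run.yaml                       # full analysis
```

and each stage is also available on its own (`spatcorr qc`, `islets`,
`density`, `divergence`, `groups`, `strauss`, `simulate`).

## Layout

```
src/spatcorr/
  data.py        transcript/nuclei I/O, quality filter, QC accounting
  islets.py      islet detection (DBSCAN + minimum enclosing circle)
  density.py     boundary-corrected KDE, symmetric KL, grouping, ranking
  strauss.py     multitype Strauss model: fitting, simulation, aggregation
  synthetic.py   ground-truth tissue and distance-sample generators
  pipeline.py    multi-timepoint orchestration with manifests
  cli.py         `spatcorr` command-line interface
docs/methods.md  model details, assumptions, numerical choices
```
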