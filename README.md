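# topodyn

**Topological contrast analysis of protein structural ensembles.**

`topodyn` detects and localizes structural differences between two ensembles
of protein conformations — typically wild-type versus mutant frames from
molecular dynamics (MD) simulations — *without* requiring atom-by-atom
correspondence between the structures. Biologically relevant changes in MD
data are easily drowned by thermal fluctuation; coordinate-based methods
(RMSF, PCA, regularized classifiers) additionally require a one-to-one atom
mapping that mutations or ligand changes can break. `topodyn` instead
summarizes each conformation by its topology and asks which topological
features statistically separate the two classes, then projects the answer
back onto atoms and residues.

It is aimed at computational structural biologists who have two sets of
frames (multi-model PDB files, or synthetic ensembles from the built-in
benchmark generator) and want a per-residue map of where the two ensembles
differ, with a permutation test for any candidate region.

## Method

For each frame the atomic point cloud is turned into a simplicial complex:
atoms are vertices, any two atoms with Euclidean distance `< r` are joined
by an edge, and every triangle of mutually connected atoms becomes a face.
All complexes are scaled into the unit ball by one common factor. For a unit
direction ν the height function h<sub>ν</sub>(x) = x·ν induces a sublevel-set
filtration with `l` thresholds spanning [−1, 1]; the Euler characteristic
(EC) curve records

> χ = #V − #E + #F

of each sublevel complex, and the **differential EC (DEC)** curve is its
lag-t difference (t = 1 by default), which tracks the local appearance and
disappearance of topological features step by step. Directions are grouped
into `c` cones of `d` directions each (cap radius θ, built by Rodrigues
rotation about near-uniform cone centers), giving J = c·d·l features per
frame and an N × J design matrix **X**.

Class labels are modelled with Gaussian process probit classification,

> y ∼ Bernoulli(π), Φ⁻¹(π) = f, f ∼ N(0, K),
> K<sub>ii′</sub> = exp(−ϑ‖x<sub>i</sub> − x<sub>i′</sub>‖²),

with the bandwidth ϑ set by the median criterion and the posterior of the
latent f sampled by elliptical slice sampling. Posterior draws are projected
to per-feature effect sizes β = X⁺f, and each feature j is scored by the
Kullback–Leibler divergence between the effect posterior and its conditional
with β<sub>j</sub> = 0 (in closed form, α<sub>j</sub>μ<sub>j</sub>²/2 with
α<sub>j</sub> = λ<sub>−j</sub>ᵀΛ<sub>−j</sub>⁻¹λ<sub>−j</sub>, computed via
exact rank-1 updates). Normalizing the KLD values to the simplex yields the
association measures γ.

Each atom maps to m = c·d features (the sublevel set in which it first
appears, per direction); its evidence score γ̂ is the minimum of those γ
values — the closed form of the threshold sweep in which an atom "dies" when
a rising threshold passes any of its features. γ̂ values are averaged over
frames, rank-scaled 0–100 per atom and per residue, and can be written into
the B-factor column of a PDB file for coloring in any molecular viewer.
Finally, a **null-region test** sums the per-atom scores in a region of
interest (ROI), compares the sum against T random K-nearest-neighbour
regions of equal size, reports the permutation P-value
P = #{τ* ≤ τ<sub>t</sub>}/(T+1), and calibrates it into an approximate Bayes
factor BF(P) = [−e·P·ln P]⁻¹ (defined for P < 1/e).

A controlled benchmark module generates synthetic thermal ensembles
(self-avoiding chain at protein density + spatially and temporally
correlated Gaussian fluctuation), perturbs a surface window of atoms either
by a constant vector (static change) or by per-frame random vectors of fixed
length (stochastic change), and scores the pipeline against RMSF, PCA, and
Elastic Net baselines by ROC AUC on the perturbed atoms.

## Worked example

Run the full pipeline on a synthetic benchmark dataset: 400-atom chain,
100 frames per class sampled 0.5 ns apart from one temporally correlated
trajectory, with a 40-atom surface window displaced by an independent 2.0 Å
random vector per atom per frame in class B:

```python
import numpy as np
from topodyn.benchmark_sim import (BenchmarkConfig, make_benchmark_dataset,
                                   choose_radius, roc_auc)
from topodyn.model import EnsembleContrast

cfg = BenchmarkConfig(seed=0)
fa, fb, truth, base, series = make_benchmark_dataset(cfg, mode="spherical",
                                                     magnitude=2.0)
r = choose_radius(base, cfg.degree_range)          # -> 4.75 A
model = EnsembleContrast(fa, fb, r=r, c=10, d=4, theta=0.80, l=60,
                         align=False, frame_series=np.r_[series, series])
res = model.fit(seed=0)
print(res.summary())
```

```
Topological Ensemble Contrast Results
=====================================================
N frames: 200  (class A: 100, class B: 100)
Features J = c*d*l: 2400  (c=10, d=4, l=60, lag=1)
Mesh radius r: 4.750 A   cone cap theta: 0.800 rad
Kernel bandwidth (median criterion): 1.1691e-04
ESS retained draws: 2000   seed: 0
-----------------------------------------------------
Top residues by evidence (gamma_hat, 0-100 score):
  residue   198   gamma_hat=6.306e-06   score=100.00
  residue   257   gamma_hat=4.995e-06   score= 99.75
  residue   247   gamma_hat=4.345e-06   score= 99.50
  residue   263   gamma_hat=4.337e-06   score= 99.25
  ...
```

The perturbed window in this dataset is residues 247–286: most of the
top-ranked residues fall inside it. Scoring every atom by the cone-wise
detection rule and comparing against the ground truth, and then testing the
window as an ROI:

```python
auc = roc_auc(res.detection_scores(), truth).auc   # -> 0.968
nt = res.roi_test("247-286", T=500)                # -> P = 0, BF = inf
```

An AUC of 0.97 means the detection scores rank perturbed atoms almost
perfectly above unperturbed ones; the null-region test says no random
40-atom region ever matched the ROI's evidence, hence the P-value of 0 and
an unbounded Bayes factor.

On real data, point the model at PDB frames instead:

```python
model = EnsembleContrast.from_pdb(["wt_frames.pdb"], ["mut_frames.pdb"],
                                  selection="heavy", r=6.0, c=20, d=8,
                                  theta=0.80, l=120)
res = model.fit(seed=0)
res.export_scored_pdb("scored.pdb")   # evidence in the B-factor column
```

or use the CLI: `topodyn run --class-a 'wt*.pdb' --class-b 'mut*.pdb'
--roi 163-178 --outdir out/`. Subcommands `benchmark`, `nulltest`,
`transform`, and `align` expose the individual stages.

## Documentation

`docs/methods.md` describes the model, the synthetic-data generator and its
limits, all tunable parameters with defaults, and the numerical choices in
detail.
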