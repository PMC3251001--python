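# midfield

Estimation of **multicomponent receptive fields** from neural responses by
**maximally informative dimensions (MID)** — with both joint and sequential
information maximization, a projection-pursuit-regression (PPR) baseline,
linear-nonlinear (LN) model-cell simulators, and subspace-overlap evaluation.

## The problem

In the LN framework a sensory neuron's spike probability depends on the
stimulus **s** (a high-dimensional vector: here, `n_lags` movie frames of
`H x W` pixels, `D = H·W·n_lags`) only through its projections onto a few
*relevant dimensions* ê₁…ê_K:

    P(spike | s) = r̄ · g(s·ê₁, …, s·ê_K)

The dimensions are estimated by maximizing the mutual information between the
projections **x** = (s·v₁, …, s·v_K) and the spike,

    I(v₁…v_K) = Σ_x P(x|spike) · log₂[ P(x|spike) / P(x) ]   [bits/spike],

with P(x) and P(x|spike) estimated as histograms; the empirical gain function
is g(x) = r̄·P(x|spike)/P(x). Because I is invariant to invertible
recombination of the v's, the object being estimated is the relevant
*subspace*. The K dimensions can be sought **jointly** (maximizing the
K-dimensional information, refreshing earlier dimensions as the search
proceeds) or **sequentially** (1D information maximization restricted to
orthogonal complements). With Gaussian stimuli the two agree; with correlated
non-Gaussian stimuli — natural movies and this package's naturalistic
surrogate — the sequential search is systematically biased and joint
optimization is required. PPR, which fits an additive model
r ≈ r̄ + Σ f_k(s·v_k) by least squares, shares the sequential strategy's
assumptions and biases.

Optimization is by simulated annealing plus gradient ascent: 1200 iterations
per dimension, histogram resolution stepping from 6 to 11 bins, temperature
cooled by 0.95 per iteration with reheating on convergence, everything
repeated on 4 jackknife folds (each omitting a contiguous quarter of the
data) and the aligned estimates averaged. Recovery is scored by the subspace
projection

    O = ( |det P| / √(det G_model · det G_recon) )^(1/K) ∈ [0, 1],

the K-th root of the normalized volume of the reconstructed unit cube
projected onto the model subspace (1 = same subspace, 0 = orthogonal).

## Worked example

```python
import numpy as np
import midfield as mf
from midfield import cells as mc

# 12,000 frames of Gaussian white noise, 8x8 pixels, 2-lag embedding (D=128)
stim = mf.generate_white_noise(12000, 8, 8, seed=3)
X = mf.embed_spatiotemporal(stim, n_lags=2).matrix

# 2D model cell: quadrature Gabor pair + OR-of-thresholds gain
cell = mc.make_or_cell(8, 8, 2)
rates = mc.rates_on(cell, X)
y = mc.simulate_spikes(rates, seed=5, family="or_threshold")

est = mf.MaximallyInformativeDimensions(
    n_dims=2, mode="joint", n_iterations=300, jackknife=False, random_state=0
).fit(X, y)

O = mf.subspace_projection(cell.dimensions, est.dimensions_).overlap
print(f"spikes: {y.sum()}")
print(f"subspace projection O = {O:.3f}")
print(f"information captured  = {est.score(X, y):.3f} bits/spike")
print(f"rate information      = {mf.info_per_spike(rates):.3f} bits/spike")
```

prints

```
spikes: 1720
subspace projection O = 0.984
information captured  = 1.350 bits/spike
rate information      = 1.377 bits/spike
```

i.e. the two Gabor filters are recovered almost perfectly (O = 0.98) and the
recovered pair captures ~98% of the information the firing rate carries
about the stimulus — the quadrature pair is a sufficient statistic for this
cell, so the small gap is binning and sampling loss.

`ProjectionPursuitRegressor` offers the additive-least-squares baseline with
the same `fit`/`predict` surface, and both estimators compose with
scikit-learn pipelines and model selection.

## Command line

```bash
midfield --seed 1 gen-stimuli --kind white_noise -T 20000 -H 12 -W 12 --out stim.h5
midfield --seed 2 simulate-cell --cell cell.json --stimuli stim.h5 --out spikes.txt
midfield --seed 3 fit --mode joint -K 2 --stimuli stim.h5 --spikes spikes.txt --out fit.h5
midfield eval overlap --model cell.json --fit fit.h5
midfield --seed 4 experiment fig1_noise --out report.json
```

Every command logs its seed and writes a manifest so runs reproduce exactly.

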