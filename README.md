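# misstaxa

Missing taxa are the rule, not the exception, in phylogenetic comparative
datasets — and because the ecological traits that govern whether a species
gets sampled (rarity, range size, habitat) themselves have phylogenetic
signal, missing taxa in real datasets are expected to be phylogenetically
clumped, or even correlated with the very trait under study. `misstaxa` is a
fully generative simulation framework for asking what such *realistic*
missing-taxa scenarios do to model selection and parameter estimation for
univariate continuous-trait evolution. It is aimed at phylogenetic
comparative biologists who want to stress-test BM/OU-type analyses against
the sampling pattern of their own data.

## The models and the design

A continuous trait *T* evolves along a unit-height pure-birth phylogeny under
one of four Gaussian models, with a binary selective regime *R* (equal-rates
Mk, rate *q* = 0.5) painted on the branches:

* **BM** — Brownian motion, rate σ²;
* **BMS** — multi-rate BM, σ²₀ → σ²₁ between regimes;
* **OU** — Ornstein–Uhlenbeck, dX = α(θ − X)dt + σ dB, pulled toward a
  single optimum θ with strength α;
* **OUM** — multi-optimum OU, θ₀ → θ₁ between regimes.

Study defaults: σ²₀ = 0.5, σ²₁ = 1, θ₀ = 10, θ₁ = 11, α = 1.5 (a
phylogenetic half-life ln 2/α ≈ 0.46 tree heights). A sampling status *S*
(0 = missing, 1 = sampled) is then drawn under one of three schemes —
**rMT** (each tip missing independently with probability *p*), **cluMT**
(the lowest *p*-quantile of a Brownian liability *L* is missing: a threshold
model, hence phylogenetically clumped), and **corMT** (exactly *p·n* tips
drawn without replacement with probability proportional to
w = t/ΣT − min T/ΣT, so high-trait tips go missing) — at *p* ∈
{0.1, 0.5, 0.9}. Trees are sized so that **300 tips always remain after
pruning**. Phylogenetic signal of *S* is measured by the Fritz–Purvis *D*
statistic (≈1 random, ≈0 threshold-like); all four models are then fit to
the pruned data by maximum likelihood (GLS with profiled scale and mean, a
single 1-D log-scale search for α or the BMS rate ratio) and compared by
AICc = −2 logL + 2k + 2k(k+1)/(n−k−1).

## A worked example

```python
import misstaxa as mt

tree = mt.simulate_yule_tree(300, seed=7)
painting = mt.simulate_mk_regimes(tree, q=0.5, seed=8)
trait = mt.simulate_trait(tree, painting, mt.ModelSpec.study_default("OUM"), seed=9)
fits = mt.fit_all(tree, painting, trait)
best, deltas = mt.select_best(list(fits.values()))
```

Running `python examples/simulate_and_fit.py` (which is this snippet plus
printing) gives:

```
model      logL  k      AICc   dAICc  estimates
BM       -16.11  2     36.27    6.77  sigma2_0=0.370, root_mean=10.669
BMS      -15.97  3     38.02    8.52  sigma2_0=0.411, sigma2_1=0.363, root_mean=10.670
OU       -12.52  3     31.12    1.63  sigma2_0=0.463, theta_0=10.680, alpha=1.103
OUM      -10.68  4     29.50    0.00  sigma2_0=0.471, theta_0=9.914, theta_1=10.727, alpha=1.241

AICc-best model: OUM
```

The generating OUM model wins (ΔAICc = 0); the optima 9.91 and 10.73 sit
near the true 10 and 11, and σ̂² ≈ 0.47 near the true 0.5. The other
scripts in `examples/` walk through the missingness schemes, the *D*
statistic calibration, and a miniature replicate experiment with the study's
summary tables. A thin CLI (`misstaxa missingness|dstat|fit|run-experiment`)
wraps the same functions for shell use; user data enter as Newick trees and
tab-separated trait/status/regime files.

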