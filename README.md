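# gpnet — graph propagational network for PPI-aware diagnosis

`gpnet` classifies samples into diagnosis groups (e.g. the dementia subtypes
MCI / AD / VD) from a small panel of plasma-protein expression values, using a
weighted protein–protein interaction (PPI) network to exploit the fact that
disease effects propagate through interacting proteins rather than acting on
proteins in isolation. It is aimed at researchers working with targeted
proteomics panels (such as Olink NPX data) together with STRING-style
interaction networks.

## Model

Let `X ∈ R^{p×n}` be the expression matrix (p proteins × n samples, the
*independent effect*) and `W ∈ R^{p×p}` the symmetric nonnegative PPI edge
weights with graph Laplacian `L = D − W` (D = diagonal of weighted degrees).
The *interactive effect* is the closed-form solution of a Laplacian-regularized
smoothing problem,

    F = argmin_F ||F − X||² + μ tr(Fᵀ L F)  =  (I + μL)⁻¹ X ,

where the smoothness `μ ≥ 0` controls how far expression is propagated
(larger μ emphasizes longer-range, higher-order interactions). A learnable
logit `α` sets the *combining ratio* `θ = σ(α) ∈ (0,1)` and the *combined
effect*

    Z = θ F + (1 − θ) X

feeds a linear softmax classifier, `P = softmax(βᵀ Z) ∈ R^{c×n}`. All
parameters (α, μ, β) are trained jointly by full-batch ADAM on the analytic
gradients of the L2-regularized cross-entropy

    𝓛 + δ𝓡 = −(1/n) tr(Yᵀ log P) + δ (α² + μ² + ||β||²) ,

with μ projected onto [0, ∞) after each step. No autodiff is used; the
gradients are closed-form (`∇β = (1/n)Z(P−Y)ᵀ + 2δβ`, and chain-rule
expressions for ∇α and ∇μ via `∂Φ⁻¹/∂μ = −Φ⁻¹LΦ⁻¹`) and are validated against
central finite differences in the test suite.

The package also provides one-vs-rest AUROC/AUPRC evaluation, a (μ, θ)
parameter-sweep surface, descriptive network statistics, and a synthetic
cohort generator that emulates the statistical shape of a dementia
plasma-proteomics study (26-protein biomarker panel, 271/121
discovery/validation split, ~70/21/8 % class imbalance, diffusion-borne class
signal), so the whole pipeline is testable without access to restricted data.

## Worked example

```python
import numpy as np
from gpnet import SimConfig, simulate_dataset, GPN, metric_report
from gpnet.simulate import one_hot

cfg = SimConfig(seed=7)                       # synthetic 26-protein cohort
net, Xd, yd, Xv, yv, truth = simulate_dataset(cfg)
Yd = one_hot(yd, cfg.class_names); Yv = one_hot(yv, cfg.class_names)

model = GPN(Xd, Yd, net, class_names=list(cfg.class_names))
res = model.fit(seed=7, eval_set=(Xv, Yv))    # grid over mu inits, ADAM training
print(res.summary())
P, labels = res.predict(Xv)
rep = metric_report(P, Yv, cfg.class_names)
print("validation macro AUROC: %.4f" % rep.auroc_macro)
```

prints

```
Graph Propagational Network Results
==============================================
proteins (p)                                26
samples (n)                                271
classes (c)                                  3
delta (L2 weight)                        0.001
mu init selected                           1.0
----------------------------------------------
alpha (combining logit)              -0.196410
theta = sigmoid(alpha)                0.451055
mu (smoothness)                       0.168832
final training loss                   0.844959
epochs run                                2000
converged (|dloss|<tol)                  False
training accuracy                       0.6531
==============================================
validation macro AUROC: 0.6407
```

The fitted combining ratio θ ≈ 0.45 means the classifier weights the
propagated (interactive) effect almost as strongly as the raw expression; the
validation AUROC is computed one-vs-rest per class and macro-averaged.

The same pipeline is available from the shell:

```sh
gpnet simulate --outdir sim --seed 7
gpnet train    sim/expression_discovery.tsv sim/labels_discovery.tsv sim/ppi_edges.tsv --outdir run
gpnet predict  sim/expression_validation.tsv run/model.json --out pred.tsv
gpnet eval     pred.tsv sim/labels_validation.tsv --out metrics.json
gpnet sweep    sim/expression_discovery.tsv sim/labels_discovery.tsv sim/ppi_edges.tsv \
               sim/expression_validation.tsv sim/labels_validation.tsv --out sweep.tsv
```

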