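# swaymf

Multifractal analysis of postural-sway displacement series: direct
(Chhabra–Jensen) spectrum estimation, IAAFT surrogate tests for
nonlinearity, block-wise cohort measures, and the associated
mixed-effects models — plus a synthetic-cohort generator with known
ground truth so the entire chain is verifiable without access to any
particular dataset.

## The problem

Postural sway — the continuous small displacement of a standing body —
is heterogeneous in time: quiet stretches alternate with bursts of
movement across many time scales. A single SD cannot describe such a
signal, and strong quasiperiodic oscillation (as in insect sway under
wind-like stimulation) makes SD-based scaling methods unreliable. This
package treats the displacement series `u(t)` (frame-to-frame Euclidean
distance of a tracked body point) as a *measure* and asks two questions:

1. **How heterogeneous is it?** At each time scale `L`, bin proportions
   `P_i(L) = Σ_bin u / Σ u` are distorted by an exponent `q` into the
   normalized mass `μ_i(q, L) = P_i^q / Σ_j P_j^q`. The scaling of the
   q-mass entropy and of the q-weighted log-proportions with `ln L`

       Σ_i μ_i ln μ_i  ~  f(q) · ln L
       Σ_i μ_i ln P_i  ~  α(q) · ln L

   gives the singularity spectrum `(α(q), f(α(q)))`; its width
   `W = α_max − α_min` is an SD-like variability index valid for
   heterogeneous, quasiperiodic signals. A `q` enters the spectrum only
   when both regressions are convincingly linear (|r| > .995), over a
   sweep `−200 ≤ q ≤ 200`.

2. **Is the heterogeneity nonlinear?** IAAFT surrogates preserve the
   series' exact value distribution and (approximately) its power
   spectrum — the best-fitting *linear* model of the data. The statistic

       t_MF = (W − mean(W_surr)) / SE(W_surr)

   is significantly positive when nonlinear interactions across time
   scales make the series *wider* (more heterogeneous) than linearly
   expectable, and significantly negative when they *constrict*
   variability below the linear expectation — the signature of
   stabilizing, sway-reducing coordination.

A cohort pipeline computes these measures for whole series (`W_ALL`,
`t_ALL`) and for consecutive 20-s blocks (`W_BLOCK`, `t_BLOCK`), and two
linear mixed-effects models (random intercept per subject, 16 fixed
terms each) test how the block course depends on experimental condition
and on the whole-series covariate: a smooth orthogonal-polynomial model
for `W_BLOCK` and a categorical-block model for `t_BLOCK`.

## Worked example

The binomial cascade is the canonical multifractal benchmark: its
spectrum width is known in closed form, `W = log2((1−p)/p)`.

```python
from swaymf import CascadeSpec, binomial_cascade, cascade_width, estimate_spectrum

w = binomial_cascade(CascadeSpec(p=0.25, k=12, seed=3))  # 4096 samples
spec = estimate_spectrum(w)
print(f"W = {spec.width:.6f}  (theory {cascade_width(0.25):.6f}), "
      f"{spec.n_retained} retained q")
```

prints

```
W = 1.584963  (theory 1.584963), 401 retained q
```

The same machinery, from the shell, on one series of a synthetic cohort
(2 subjects, 4012 samples each):

```sh
swaymf simulate --spec spec.yaml --seed 4 demo/      # spec.yaml: n_subjects: 2, series_length: 4012
swaymf spectrum demo/S01_c1.csv demo/S01_spec
swaymf surrogate -n 5 --iterations 50 --seed 2 demo/S01_c1.csv demo/S01_surr
```

```
W = 0.234835 over 21 retained q
t = 1.4358 (W = 0.234835, surrogate mean = 0.230282, se_mode = se)
```

Here `W` is the spectrum width of that series over the retained q, and
`t` compares it to 5 IAAFT surrogates: positive but below the two-sided
1.96 cut, i.e. no evidence of nonlinearity at this (deliberately tiny)
ensemble size. `swaymf analyze` runs the whole cohort into a modeling
table; `swaymf model` fits either mixed model from that table.

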