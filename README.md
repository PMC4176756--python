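# qsabr

Quantitative structure–activation-barrier relationship (QSABR) modelling
for Diels-Alder ligations.

Diels-Alder [4+2] cycloadditions between a conjugated diene and a
dienophile are workhorse click/bioconjugation reactions, and the activation
free energy ΔG‡ (kcal/mol) decides which diene–dienophile pairs are worth
synthesising. Computing ΔG‡ through transition-state theory is expensive
and often fails to converge; `qsabr` implements the cheap alternative:
regress ΔG‡ on frontier-orbital descriptors of the *separated* reactants.

From each reactant's HOMO/LUMO eigenvalues (hartree) and dipole moment
(Debye) the package computes the conceptual-DFT reactivity indices

- chemical potential μ = (E_LUMO + E_HOMO)/2 and electronegativity χ = −μ,
- hardness η = (E_LUMO − E_HOMO)/2 and softness SOF = 1/η,
- electrophilicity ω = χ²/(2η),
- the Sustmann orbital-interaction term
  ΔE = [(HOMO_d−LUMO_a) + (HOMO_a−LUMO_d)] / [(HOMO_d−LUMO_a)(HOMO_a−LUMO_d)],

and assembles a frozen 24-descriptor catalogue per reaction (per-reactant
values plus diene-minus-dienophile differences). On top of that sit:

- **regression** — OLS with full diagnostics, closed-form leave-one-out
  validation (PRESS, Q² = 1 − PRESS/TSS), external predictivity R²_pred
  against the training mean, a pairwise collinearity filter, and greedy
  forward–backward stepwise selection by partial-F tests
  (α-to-enter = α-to-remove = 0.25 by default);
- **published_models** — the two published barrier equations (6 and 7
  descriptor terms, intercepts −6.4 and −121.3 kcal/mol) bundled as frozen
  predictors with their reported statistics;
- **bpann** — a from-scratch one-hidden-layer sigmoid network trained by
  online back-propagation with momentum
  (Δw = φ·δ·out + γ·Δw_prev; defaults 5 hidden neurons, φ = 0.6, γ = 0.2,
  4800 epochs, seeded and bit-reproducible);
- **applicability_domain** — Williams-plot assessment: leverages
  h = xᵀ(XᵀX)⁻¹x, warning leverage h* = 3(n_desc+1)/n_obs, standardized
  residuals, in/out-of-domain flags;
- **synthetic_data** — seeded generators of physically plausible reactant
  pools and reaction sets with known ground truth, including a
  72-reaction, 55/17-split benchmark.

## Worked example

```python
import numpy as np
from qsabr import (ReactantElectronicRecord, descriptor_vector, eq10_model,
                   predict_barrier, fit_ols, r2_pred, make_benchmark)

# descriptors for one pair
diene = ReactantElectronicRecord("butadiene", "diene", -0.32, 0.11, 0.0)
enone = ReactantElectronicRecord("mvk", "dienophile", -0.38, 0.02, 3.0)
dv = descriptor_vector(diene, enone)
print(round(dv["omega_a"], 4), round(dv["d_homo"], 2))
# 0.081 0.06

# published 7-term model applied to that pair
print(round(predict_barrier(eq10_model(), dv), 1))
# 21.2

# benchmark with known truth: fit the true support, validate
b = make_benchmark("paper_like_linear", seed=1)
names = list(b.true_support)
m = fit_ols(b.train[names], b.train["dg_exp"].to_numpy())
m.r2_pred = r2_pred(m, b.test[names], b.test["dg_exp"].to_numpy())
print(f"R2={m.r2:.3f}  Q2_loo={m.q2_loo:.3f}  R2_pred={m.r2_pred:.3f}")
# R2=0.995  Q2_loo=0.994  R2_pred=0.989
```

The first line prints the dienophile's electrophilicity (atomic units) and
the HOMO-level difference; the second the predicted barrier in kcal/mol
(subject to the descriptor-unit caveat in `docs/methods.md`); the last the
training fit, its leave-one-out cross-validation and the external test-set
predictivity on synthetic data whose generating model is known.

The same workflow is available from the shell:

```sh
qsabr simulate --preset paper_like_linear --seed 1 --out-dir bench/
qsabr fit --matrix bench/descriptors.csv --stepwise --model-out model.json
qsabr predict --model eq10 --matrix bench/descriptors.csv --out pred.csv
qsabr ad --model model.json --train bench/descriptors.csv --out ad.csv
```

## Layout

| module | contents |
| --- | --- |
| `qsabr.records` | reactant/reaction records and invariants |
| `qsabr.reactant_io` | CSV/TSV tables, eV→hartree conversion, QC-log reader |
| `qsabr.descriptors` | reactivity indices, Sustmann ΔE, 24-descriptor catalogue |
| `qsabr.regression` | OLS, PRESS/Q², R²_pred, collinearity filter, stepwise |
| `qsabr.published_models` | the two frozen barrier equations |
| `qsabr.bpann` | back-propagation network, scaling, LOO RMS |
| `qsabr.applicability_domain` | leverages, h*, Williams table and plot |
| `qsabr.synthetic_data` | seeded generators and benchmark presets |
| `qsabr.cli` | `qsabr` command-line interface |

`docs/methods.md` documents the model equations, defaults, numerical
choices and known limitations.
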