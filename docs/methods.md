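# Methods

## The modelling problem

A Diels-Alder ligation couples a conjugated diene with an electron-poor
alkene (the dienophile). Its activation free energy ΔG‡ (kcal/mol) controls
the reaction rate and hence whether a candidate pair is useful as a click
ligation. Locating transition states quantum-chemically is expensive and
fragile; this package instead regresses ΔG‡ on descriptors computed from
the *separated* reactants' frontier orbitals — a
structure–activation-barrier relationship.

## Descriptors

Each reactant is summarised by its HOMO and LUMO eigenvalues (hartree) and
total dipole moment (Debye). From Koopmans' relations (I = −E_HOMO,
A = −E_LUMO) the global reactivity indices follow in closed form:

    μ   = (E_LUMO + E_HOMO)/2        chemical potential
    χ   = −μ                         electronegativity
    η   = (E_LUMO − E_HOMO)/2 > 0    absolute hardness
    SOF = 1/η                        softness
    ω   = χ²/(2η)                    electrophilicity

For a pair, the Sustmann orbital-interaction term combines the two cross
gaps g₁ = HOMO_d − LUMO_a, g₂ = HOMO_a − LUMO_d:

    ΔE = (g₁ + g₂)/(g₁·g₂)

The public vocabulary is a frozen 24-entry catalogue: the four frontier
energies, the two cross gaps, ΔE, per-reactant η, χ, ω, SOF, dipole, and
the diene-minus-dienophile difference of each per-reactant quantity. All
orbital-derived descriptors are carried in atomic units, dipoles in Debye;
the engine never rescales. Difference entries are recomputed from their
primitives at construction, so the antisymmetry under reactant exchange and
the identity chain (SOF·η = 1, 2ηω = χ²) hold to machine precision and are
asserted as property tests.

A deliberate consequence of the catalogue design: the difference columns
are *exact* linear combinations of their primitive columns
(e.g. ω_d − ω_a = ω_d − ω_a holds as column arithmetic for any dataset).
The full 24-column design is therefore always rank-deficient, which shapes
the variable-selection behaviour discussed below.

## Linear modelling and validation

Ordinary least squares with an intercept, fitted through statsmodels.
Diagnostics use the n−p−1 conventions: R² (explained variance), the
regression F, the standard error of regression SE, and per-coefficient
standard errors. Leave-one-out validation uses the closed-form deleted
residual e_i/(1 − h_ii) (h_ii the hat-matrix diagonal), giving PRESS and
Q² = 1 − PRESS/TSS without n refits; a brute-force refit oracle in the test
suite confirms equality to 1e-8 relative. Since PRESS ≥ RSS whenever
0 < h_ii < 1, Q² ≤ R² on every fitted model — asserted across a random
model family. External predictivity R²_pred centres the held-out responses
on the *training* mean, so a model no better than that mean scores zero.

### Collinearity filter

A greedy pass in catalogue order keeps a descriptor only if its absolute
Pearson correlation with every already-kept descriptor is at or below the
threshold (default |r| ≤ 0.99); the later column of an offending pair is
dropped, and zero-variance columns are dropped with a warning. Pairwise
filtering deliberately does not attempt to break the exact *multivariate*
dependencies above.

### Stepwise search

Greedy forward–backward selection driven by partial-F tests. The
entry/removal thresholds are significance levels α-to-enter = α-to-remove
= 0.25 by default — the Minitab stepwise convention; a raw-F mode
(`criterion="f"`) is available for dialects that threshold the F value
itself. Forward: the candidate with the smallest partial-F p-value enters
if p ≤ α_enter. Backward after every addition: the included variable with
the largest p is removed while p > α_remove. LOO Q² is recorded at every
step for monitoring but never drives the search (selection is by partial F
alone; recording Q² per step keeps the model-quality trace inspectable
without making the search criterion circular).

Numerical choices:

- Candidates whose addition makes the (intercept-augmented) design rank
  deficient are skipped — their partial F is undefined. This is what lets
  the search run on the full, exactly-collinear 24-descriptor catalogue.
- p-value ties — including ties at exactly 0 from floating-point underflow
  under very strong signals — resolve to the larger partial F, then to the
  lower catalogue index. Without the F tie-break, underflow would make the
  entry order follow catalogue order rather than strength of association.
- RSS improvements below 1e-12 of the total sum of squares are treated as
  zero, so a numerically perfect fit terminates the search rather than
  admitting variables that "explain" rounding residue at machine epsilon.
- Rank-deficient designs passed directly to `fit_ols` are errors, never
  silently pseudo-inverted.

## Published barrier equations

Two frozen predictors ship with the package: a six-term equation fitted on
the original 72-reaction compilation (intercept −6.4; reported R² = 0.831,
Q²_LOO = 0.784, SE = 2.30) and a seven-term equation fitted on its
55-reaction training split (intercept −121.3; reported R² = 0.865,
Q²_LOO = 0.800, SE = 2.06, external R²_pred = 0.880 on 17 test reactions).
Coefficients are stored at printed precision and audited bit-for-bit by a
transcription test. They are not refittable here: the descriptor values
behind the original fits were never published.

Known caveats, documented rather than modelled:

- The unit system of the original descriptor matrix is unstated. The
  coefficient magnitudes are consistent with atomic-unit descriptors, and
  this package assumes that convention, but predictions on user data are
  not guaranteed commensurate with the original kcal/mol barriers.
- Descriptors of the separated reactants barely change with solvent, so
  the equations cannot distinguish the same reaction run in different
  solvents even when measured barriers differ.

## Back-propagation network

A from-scratch one-hidden-layer sigmoid network trained online: after each
object, every weight receives Δw = φ·δ·out_prev + γ·Δw_prev, with δ the
back-propagated derivative of the squared error through the sigmoid (the
½ factor absorbed into δ) and a fixed bias input of 1 contributing the
(n+1)-th term of each net input. Defaults follow the reference protocol:
5 hidden neurons, learning rate φ = 0.6, momentum γ = 0.2, 4800 epochs,
objects in dataset order (a seeded per-epoch shuffle is optional, off by
default). An optional linear decay schedule for φ and γ exists but is off
by default because the final protocol uses fixed values.

Inputs are min-max scaled to [0,1] on training ranges; targets to
[0.1, 0.9] to stay off the sigmoid asymptotes (a constant target is given
a unit-wide band centred on its value). Queries outside the training range
are mapped by the same affine transform and flagged. Weights initialise
uniformly in [−0.5, 0.5] from the config seed; training is bit-reproducible
under the seed. Correctness of the update is established against central
finite differences of ½(t − out)² (γ = 0, 1e-4 relative, 50 random nets).
Non-finite weights abort with the epoch number rather than propagating
NaNs. Leave-one-out RMS trains one fresh network per fold, with fold seeds
derived deterministically from the config seed.

## Applicability domain

Leverage of an object with intercept-augmented descriptor row x is
h = xᵀ(XᵀX)⁻¹x against the training design X (the printed source formula
is truncated after the inverse; the standard quadratic form is intended
and implemented). Warning leverage h* = 3(n_desc + 1)/n_obs. Standardized
residuals divide by s√(1 − h_ii) for training objects and by s for
external objects; the cut-off defaults to ±3, the conventional
Williams-plot choice. Prediction-set objects without measured barriers are
assessed on leverage only. The Williams table (leverage vs standardized
residual with h* and ±cut-off guides) is returned tidy and can be rendered
with `plot_williams`.

## Synthetic benchmark

`make_benchmark("paper_like_linear", seed)` draws 9 dienes and 9
dienophiles with uniform HOMO ∈ [−0.45, −0.25] hartree, LUMO ∈ [−0.10,
0.15] hartree (ranges disjoint, so every record has a positive gap without
rejection sampling) and dipole ∈ [0, 6] Debye; pairs 72 distinct reactions;
splits 55/17 train/test by a seeded permutation; and generates barriers
from a linear truth over {ΔLUMO, ω_a, ω_d−ω_a, LUMO_d, ΔE, SOF_d, DM_a}
with realistic coefficient magnitudes (hundreds of kcal/mol per hartree-
scale descriptor, fractions per Debye) plus Gaussian noise of SD
2.0 kcal/mol — pegged to the ≈2 kcal/mol regression SE typical of barrier
fits at this scale. `paper_like_nonlinear` adds a quadratic dipole term.
Uniform draws keep every record physically admissible; pair sampling is
without replacement; everything is deterministic under the seed.

What the generator does *not* emulate: real orbital energies are not
independent uniforms (conjugation correlates HOMO and LUMO), real
compilations reuse reactants unevenly, solvent shifts descriptors slightly,
and real barrier noise is not homoscedastic Gaussian. Passing tests
therefore demonstrate correctness of the machinery and statistical
behaviour under known truth — not chemical accuracy on new reactions.

### What recovery experiments can and cannot show

Because the catalogue's difference columns are exact linear combinations of
their primitives, the benchmark truth admits exactly equivalent named
reparametrizations: {ΔLUMO, ω_a, ω_d−ω_a, LUMO_d, …} and {LUMO_a, LUMO_d,
ω_d, ω_a, …} produce identical fitted functions (verified to 4e-12 in the
test data). Named-support recovery is therefore not identifiable: a greedy
search legitimately selects an equivalent set, and measured named recovery
(≥5 of 7 true names) sits near 15% of seeded replicates at any noise
level. Recovery modulo span — each true descriptor column lying in the
span of the selected columns plus intercept — is the meaningful measure
and sits near 80%. Both rates are computed and reported by
`scripts/acceptance.py`; OLS on the true named support (full rank) covers
every generative coefficient within 3 standard errors in ≈97–99% of
replicates, as standard theory predicts.

## Problem sizes

The shipped experiments use the benchmark at its native scale (72
reactions), 100 seeded replicates for selection/coverage rates, 100 random
instances for the LOO oracle comparison, 50 random nets for the gradient
check, and a single default-schedule network training (55 × 4800 online
updates) for the ANN/OLS parity check. These sizes give stable rates while
keeping a full run of the suite and the acceptance script to a few
minutes on one CPU.

## Known limitations

- The bundled equations interpolate the original study's chemistry
  (non-catalysed Diels-Alder reactions in four solvents); the
  applicability-domain tools exist precisely because extrapolation beyond
  it is unreliable.
- The QC-log reader handles the common Gaussian-style eigenvalue/dipole
  layout (final occupied/virtual blocks, `Tot=` dipole) and nothing more
  exotic (no ONIOM, no open-shell β blocks).
- The ANN reproduces the training *protocol*; exact reproduction of the
  original RMS figures is impossible because the original scaling, weight
  initialisation and object order were never reported.
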