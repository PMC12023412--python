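# Methods

## Model family

The correction treats the experimental stability change of a
single-point mutation w→m as the sum of a folded-state term — what a
potential-like base predictor measures — and an unfolded-state term
approximated by independent per-residue contributions of the two
swapped amino acids. With the occurrence encoding O (−1 at the
wild-type residue, +1 at the mutant, 0 elsewhere, alphabetical
one-letter order) the three fitted forms are

- **dd** (data-driven): ΔΔG = a₀·ΔS + Σᵢ aᵢ·Oᵢ, 21 coefficients;
- **rose**: ΔΔG = a₀·ΔS + a₁·(R_m − R_w), two coefficients with R a
  fixed per-residue scale;
- **only**: ΔΔG = Σᵢ aᵢ·Oᵢ, the residue term alone, useful as a
  no-method baseline.

ΔS is the base method's score difference in its own units; a₀ rescales
it into kcal/mol. The forms are odd functions of the mutation
direction, so antisymmetry (reverse mutation ⇒ negated prediction) is
structural, not learned, and holds to floating-point precision for any
coefficient values.

### Identifiability

Each row of the occurrence block sums to zero, which has two
consequences. First, the 20 residue coefficients are identifiable only
up to a shared additive constant; predictions are invariant to that
gauge, so comparisons of coefficient vectors (across base methods, or
against hydrophobicity scales) use Pearson correlation, which is
shift-invariant. Second, the occurrence block is rank-deficient (rank
≤ 19), so ordinary least squares on the dd/only designs is singular:
the solver refuses λ = 0 on a rank-deficient design and directs the
caller to λ > 0 rather than silently returning one of infinitely many
solutions.

## Fitting

Coefficients minimize ‖y − Xβ‖² + λ‖β‖² via the normal equations; the
solver is exact, not iterative, and is verified in the tests against
an independent numerical minimizer of the same objective. Choices that
matter:

- **No intercept, in any mode.** A constant term would break exact
  antisymmetry. Antisymmetric augmentation of the training set (see
  below) would drive a fitted intercept toward zero anyway; the
  package enforces zero structurally.
- **Penalty λ = 1.0 by default** for dd/only (in squared-kcal/mol per
  squared-coefficient units; the conventional default of off-the-shelf
  ridge implementations), and λ = 0 for the two-parameter rose mode,
  which is far from singular. Both are configurable; λ = 0 reproduces
  plain least squares where the design permits it.
- **The penalty counts per input record.** When augmentation doubles
  the rows, the raw penalty is doubled with them, so the no-intercept
  fit is *exactly* invariant to augmentation. Without this scaling,
  duplication would dilute the penalty and the "augmentation changes
  nothing" property would hold only approximately.
- **No feature standardization.** Occurrence features are already on a
  ±1 scale and coefficients stay interpretable in kcal/mol.
- **No silent row-dropping.** Records missing a field the mode needs
  abort the fit with the offending ids (strict default); lenient
  parsing is an explicit opt-in at read time, because training on
  silently dropped rows changes coefficients.

### Antisymmetric augmentation

`augment_antisymmetric` appends, for every mutation, its reverse with
negated experimental ΔΔG. Per-state scores are swapped; the score
*delta* is negated rather than recomputed, since in the retrofit
setting only direct predictions of the base method exist — a
documented approximation. Augmentation is on by default during
fitting (and provably a no-op for the coefficients given the scaling
above); it matters only if an intercept policy were ever enabled.

### Sign conventions

The package never normalizes the ΔΔG sign convention of an input
table. The convention label travels as free text in dataset metadata;
the linear model is convention-agnostic (flipping all signs flips the
coefficients). Silent sign-flipping is the classic source of
ΔΔG-benchmark bugs, so it is left to the user, visibly.

## Scales

The Rose scale (mean side-chain area buried on folding, Å²) and the
Kyte–Doolittle hydropathy index are transcribed from their original
publications and shipped as versioned constants with provenance
comments; no solvent-accessibility computation is performed. Raw
transcribed values are used unrescaled — the fitted a₁ absorbs any
linear rescaling of the scale. Note that Kyte–Doolittle assigns the
same value (−3.5) to D, E, N and Q, so a zero scale-delta does not
imply an identity mutation for that scale; the Rose scale's 20 values
are distinct. Custom scales can be registered from two-column TSV
files.

## Evaluation

PCC and RMSE are computed on paired experimental/predicted lists;
zero-variance or too-short inputs raise typed errors instead of
returning NaN, so degenerate comparisons cannot leak into reports.
Antisymmetry is reported in the established direct/inverse convention:
the correlation between direct predictions and negated reverse
predictions, plus the mean of (direct + inverse)/2 as a bias in
kcal/mol. Both equal their ideal values (1, 0) to machine precision
for every model in this family, by construction.

## Synthetic benchmark generator

The generator emulates a merged training benchmark of 3322 single-point
mutations (its default size) so that fitting, recovery and the
performance effect of the correction are testable without downloads.
Per record:

- a (wt, mut) pair drawn uniformly from the 380 ordered residue pairs
  — uniform rather than benchmark-skewed, so every coefficient is
  identifiable at moderate n;
- a folded-state effect f ~ N(0, σ_fold²), σ_fold = 1.5 kcal/mol;
- an unfolded-state term u[mut] − u[wt], where u defaults to the Rose
  scale linearly rescaled to span [−2, 2] kcal/mol — a realistic
  solvation-like signal correlated with real chemistry;
- observed ΔΔG = f + u-term + N(0, σ_obs²), σ_obs = 0.5 kcal/mol;
- a base-method score delta: the component of f the method captures,
  divided by the planted weight a₀ = 0.8 so the score lives in "method
  units". The method's own error (σ_score = 0.8 method units) is the
  component of f the score does *not* capture.

The last point is a deliberate design choice: the method error is
placed in the response, not the regressor. Noise added to the
regressor would attenuate the fitted a₀ toward zero by the standard
errors-in-variables mechanism — a bias that says nothing about the
correction being tested and would make the planted a₀ unrecoverable
in principle. With the chosen placement, least squares is consistent
for a₀, and the decomposition keeps the stated σ_fold as the total sd
of the folded effect (which requires a₀·σ_score ≤ σ_fold; the
configuration validates this). All stated noise magnitudes and the
closed-form variance of the observed ΔΔG are unchanged by this
placement.

All draws flow through one seeded generator, so a configuration and
seed reproduce a table byte for byte.

### What the generator does and does not emulate

It reproduces the *structure* the correction assumes: additive
folded/unfolded decomposition, per-residue unfolded contributions,
Gaussian noise. It does not emulate real benchmarks' composition skew
(some substitutions are heavily over-represented), position- or
structure-dependent effects, heteroscedastic experimental error, or
any specific base predictor's error correlations. Passing recovery
tests therefore demonstrates that the machinery is correct and the
parameters identifiable under the model's own assumptions — not that
a particular base method will improve by a particular margin on a
particular real benchmark.

### Recovery experiment

`recovery_experiment` draws a training and an independent test table
per seed, fits the dd model (λ = 1.0, augmented), and reports the PCC
of the raw score and of the corrected prediction on the test table,
the correlation between fitted and planted residue coefficients, and
the relative a₀ error. At default settings (20 seeds) the corrected
predictor beats the raw score in every seed by ≈ 0.3 PCC, coefficient
recovery correlation exceeds 0.99, and the aggregate a₀ error is
≈ 1%; with the planted u set to zero the correction neither helps nor
hurts (ΔPCC within ±0.02 of zero). Problem sizes in the shipped tests
and acceptance script (n = 3322 per draw, 20 seeds; one consistency
check at n = 20000) were chosen to make these statistics stable while
keeping a full run in the seconds-to-minutes range.

## Numerical and interface details

- Model files are JSON keyed by residue letter (order-free,
  schema-versioned); floats serialize via `repr`, so save → load is
  bit-exact. Table CSV uses `repr` floats and round-trip float parsing
  for the same reason.
- All CLI outputs are written atomically (temp file + rename).
- Residue symbols are case-insensitive on input, normalized to
  uppercase; ambiguity codes and non-canonical residues (B, Z, X, U,
  O) are rejected, never imputed.
- Positions are stored verbatim from the source file (no 0/1-based
  conversion): the model never uses them numerically, and conversion
  would be another silent-corruption vector.
- Dataset merging keys on (structure, chain, position, wt, mut) with
  primary-dataset precedence on collisions and a reported
  kept/overridden count.

## Known limitations

- The correction is zero-order: per-residue, position-independent,
  with no interaction terms. Mutations whose unfolded-state effect
  depends on sequence context are outside the model.
- The complement's score delta is the negated direct delta; for base
  methods whose direct and reverse predictions genuinely differ, the
  augmented rows understate that asymmetry.
- Per-residue coefficients from ridge with λ > 0 are slightly shrunk
  toward zero; interpret magnitudes with that in mind (the gauge
  ambiguity already precludes reading them as absolute energies).
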