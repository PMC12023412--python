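# mbcorrect

Mass-balance correction of potential-like protein stability (ΔΔG)
predictors.

## The problem

Fast "potential-like" predictors of the stability change upon a
single-point mutation — knowledge-based potentials, inverse-folding
protein-language models, zero-shot networks — score only the folded
structure, approximating

    ΔΔG ≈ G_F(m) − G_F(w)

and silently dropping the free-energy difference between the *unfolded*
states of the two sequences. Dropping that term violates mass balance
for the exchange reaction the measurement describes, and it measurably
costs accuracy.

This package retrofits any such predictor with an additive,
antisymmetric correction that approximates the unfolded-state term by
per-residue contributions of the two swapped amino acids. It is aimed
at people who benchmark or deploy ΔΔG predictors and already have the
base method's scores in a table; the base predictors themselves are
never run here.

## The model

A mutation w→m is encoded as a 20-element occurrence vector *O* (fixed
alphabetical residue order): −1 at the wild-type residue, +1 at the
mutant, 0 elsewhere. Three model forms are supported, with S the base
method's score and ΔS = S_m − S_w:

| mode   | prediction (kcal/mol)             | parameters |
|--------|-----------------------------------|------------|
| `dd`   | a₀·ΔS + Σᵢ aᵢ·Oᵢ                  | 21         |
| `rose` | a₀·ΔS + a₁·(R_m − R_w)            | 2          |
| `only` | Σᵢ aᵢ·Oᵢ                          | 20         |

where R is a fixed per-residue scale — by default the Rose mean
area buried on folding, an experimental proxy for solvation cost (the
Kyte–Doolittle hydropathy scale is also built in). Coefficients are fit
by closed-form ridge regression with no intercept, so every model is
*exactly* antisymmetric: predicting the reverse mutation negates the
prediction. Because Σᵢ Oᵢ = 0, the residue coefficients carry a gauge
freedom (a shared additive constant changes nothing); compare them
across methods by correlation, not by value.

Evaluation uses the field's standard metrics — Pearson correlation
(PCC) and RMSE in kcal/mol — plus direct/inverse antisymmetry
diagnostics. A synthetic-benchmark generator with a planted
unfolded-state signal makes the whole pipeline testable without any
external datasets.

## Worked example

Generate a synthetic training benchmark (3322 mutations, the size of
the merged benchmark the generator emulates), fit the 21-coefficient
correction, and score a held-out draw:

```sh
mbcorrect synth --out train.csv --n 3322 --seed 1
mbcorrect synth --out test.csv  --n 1000 --seed 99
mbcorrect fit --in train.csv --mode dd --lambda 1.0 --out model.json
mbcorrect predict --model model.json --in test.csv --out pred.csv
mbcorrect eval --pred pred.csv
```

prints

```json
{
  "n": 1000,
  "pcc": 0.9245990574493422,
  "rmse": 0.8079677205591876,
  "antisymmetry": null
}
```

The raw base-method score alone reaches PCC 0.6437 on the same test
table, so the correction recovers most of the planted unfolded-state
signal. The fitted model file reports a₀ = 0.7806 against a
planted score weight of 0.8, and residue coefficients in kcal/mol
(e.g. G −1.70, W +2.18: burying a large aromatic side chain is
expensive, swapping in a glycine is not).

The same `fit`/`predict`/`eval` pipeline runs on real benchmark tables:
any CSV/TSV with wild-type, mutant, position, experimental ΔΔG and the
base method's score columns (or a compact `A123V` mutation column) can
be mapped onto the canonical dialect — see `mbcorrect fit --help`.
Cross-benchmark protocols (fit on one dataset's predictions, evaluate
on another, per method) are plain compositions of these subcommands.

## Layout

- `src/mbcorrect/scales.py` — canonical residues, Kyte–Doolittle and
  Rose scales, custom-scale registry (TSV import/export)
- `src/mbcorrect/dataset_io.py` — mutation tables, merging with
  precedence, antisymmetric augmentation, model JSON
- `src/mbcorrect/core.py` — occurrence encoding, design matrices,
  ridge solver, fit/predict
- `src/mbcorrect/evaluation.py` — PCC, RMSE, antisymmetry metrics,
  coefficient correlations
- `src/mbcorrect/synthetic.py` — planted-signal benchmark generator
  and recovery experiments
- `src/mbcorrect/cli.py` — `mbcorrect synth|fit|predict|eval`

See `docs/methods.md` for the model's assumptions, parameter defaults
and known limitations.
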