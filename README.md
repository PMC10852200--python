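# idakit

Population-level prediction of cancer drug-combination efficacy from
monotherapy cell-line screening data, under the assumption of **independent
drug action (IDA)**.

Exhaustively screening drug combinations in the lab is impractical: the
number of candidate pairs grows quadratically in the drug catalogue, and
each pair needs a full concentration grid across a cell-line panel. IDA
sidesteps the combinatorics with a hypothesis that has held up remarkably
well against clinical-trial outcomes: *a combination's baseline efficacy in
a given model is simply the effect of its single best component drug* — no
synergy, no additivity. Under IDA, an ordinary monotherapy viability screen
(hundreds of cell lines × drugs × doses, in the style of CTRPv2, GDSC or
PRISM) already contains everything needed to predict combination efficacy
across a heterogeneous population: drugs combine well exactly when they
kill *different* subpopulations of models.

idakit is for computational pharmacologists and drug-repurposing
researchers who have such a screen (their own, or one exported from a
public resource) and want ranked, reproducible combination predictions
from the command line or from Python.

## The model

For a treatment $T = \{(d_1, c_1), \dots, (d_k, c_k)\}$ of drugs $d_j$ at
concentrations $c_j$, and a model (cell line) $i$ with measured monotherapy
efficacies $e_i(d_j, c_j)$:

- **IDA combination rule** (viability-like metric, lower = better):
  $e_i(T) = \min_j \, e_i(d_j, c_j)$ (the maximum for higher-is-better
  metrics). Predictions use only models measured for *every* component.
- **Population efficacy**: $\bar e(T) = \tfrac1n \sum_i e_i(T)$, an
  unweighted mean over the $n$ evaluable models. All reported efficacies
  are population averages, never per-patient predictions.
- **Hazard ratio** of a test therapy vs a control:
  $\mathrm{HR} = S(\text{test}) / S(\text{control})$, where the survival
  fraction $S$ is $\bar e$ itself for viability-like metrics and
  $1 - \bar e$ otherwise. HR = 1 means no benefit; lower is better. HRs
  are only well defined for metrics in $[0, 1]$; negative mean survival is
  reported as a domain error, and a control survival of exactly 0 yields an
  explicit "undefined" flag rather than infinity.
- **IDAComboscore**, for ranking combinations that lack a shared control:
  $(S_{\text{control}} - S_{\text{combo}}) \times |1 - \mathrm{HR}|$ —
  rewards additional cell death over the control, penalizes high HR, is 0
  when the combination matches its control and negative when it is worse.
  Higher is better.

Three workflows wrap these primitives: **two-drug** (one pair over a
concentration grid, or one anchor drug against many candidates ranked at
maximum concentrations), **control-plus-one** (the benefit of adding one
drug to an existing therapy, with HRs against both the control and the
added drug alone), and **test-vs-control** (two arbitrary therapies, as in
a clinical-trial comparison). Concentration ranges can be capped per drug
at a clinically sustainable plasma concentration (Csustained) before
ranking. A seeded synthetic-screen generator (Hill dose-response curves,
heterogeneous sensitivity classes, tunable between-mechanism correlation)
provides ground-truth data for testing and exploration.

## Worked example

Simulate a 200-line screen with two anti-correlated drug mechanisms
(correlation −0.5, so the two drugs tend to kill different cell lines),
then rank drugB as a partner for drugA:

```sh
idakit simulate --n-models 200 --correlation -0.5 --noise-sd 0.02 \
    --seed 11 --out screen.tsv
idakit two-drug --screen screen.tsv --lower-is-better \
    --anchor-drug drugA --candidates drugB --out-dir out
```

`out/two_drug_ranking.tsv` (the pair at each drug's maximum tested
concentration):

```
drug_a  drug_b  conc_a  conc_b  mean_efficacy_a  mean_efficacy_b  mean_efficacy_combo  hr_vs_control  idacomboscore  n_models  label
drugA   drugB   10.0    10.0    0.4437           0.4348           0.1721               0.3959         0.1586         200       drugA@10 + drugB@10
```

Each monotherapy alone leaves ~44% of cells viable on average, but because
the two drugs kill largely complementary cell lines, the IDA-predicted
combination drops mean viability to 0.172 — an HR of 0.396 versus the
better monotherapy (a 60% reduction in surviving fraction) and an
IDAComboscore of 0.159. The full grid (`out/two_drug_full.tsv`) shows the
same prediction at all 3 × 3 concentration pairs: at the lowest doses the
combination adds nothing (HR ≈ 0.98, score ≈ 0.0002), and the benefit
grows monotonically with dose.

The same engine is available from Python:

```python
from idakit import Treatment, combo_metrics, load_screen

screen = load_screen("screen.tsv", lower_is_better=True)
m = combo_metrics(
    screen,
    test=Treatment((("drugA", 10.0), ("drugB", 10.0))),
    control=Treatment((("drugA", 10.0),)),
)
print(m.hazard_ratio, m.idacomboscore, m.n_models)
```

## Input format

Screens are tab- or comma-delimited UTF-8 tables (dialect autodetected
from `.tsv`/`.csv`) with a header row and exact column names `model_id`,
`drug`, `concentration` (µM), `efficacy`, optional `cancer_type`. The
metric orientation (`--lower-is-better` / `--higher-is-better`) must be
stated explicitly — it has no default because mis-setting it silently
flips every hazard ratio. Concentration caps are two-column tables
(`drug`, `max_concentration`). Requested concentrations must match tested
doses exactly (relative tolerance 1e-6); idakit never interpolates
between doses.

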