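# Methods

## The independent-drug-action engine

idakit predicts combination efficacy under independent drug action (IDA):
in each model the combination does exactly what its best single component
does. Formally, for treatment components $(d_j, c_j)$ and per-model
monotherapy efficacies $e_i(d_j, c_j)$, the per-model combination efficacy
is $\min_j e_i(d_j, c_j)$ when lower efficacy means stronger effect
(viability-like metrics) and $\max_j$ otherwise. The rule generalizes to
any number of components; a treatment of one drug returns the monotherapy
unchanged, and duplicate (drug, concentration) components are collapsed on
construction, so self-combination is the identity.

Assumptions worth keeping in mind:

- **Population level only.** Reported efficacies are unweighted arithmetic
  means across the evaluable models. Nothing here predicts the response of
  an individual line or patient.
- **Evaluable models.** A prediction uses only the models measured for
  every component of every treatment in the comparison, and both arms of a
  comparison always share one model set. This makes comparisons internally
  consistent but means the population can change when the treatment set
  changes.
- **No pharmacology of interaction.** No synergy, antagonism, or
  pharmacokinetic interaction is modelled; IDA is the baseline that
  clinical combination data have repeatedly been consistent with.

### Metrics

With survival fraction $S = \bar e$ (viability-like) or $1 - \bar e$
(higher-is-better):

- $\mathrm{HR} = S_{\text{test}} / S_{\text{control}}$. HRs are only
  meaningful for efficacy metrics in $[0, 1]$: a negative mean survival
  raises a domain error rather than producing a nonsensical ratio, and
  $S_{\text{control}} = 0$ yields an explicit undefined flag (`None` in
  the API, an empty cell plus `undefined_hr` flag in batch tables) rather
  than infinity, so batch outputs stay machine-readable.
- $\text{IDAComboscore} = (S_{\text{control}} - S_{\text{combo}})
  \times |1 - \mathrm{HR}|$. The score must be strictly increasing in
  added cell death, strictly decreasing in HR, zero at parity, and
  negative when the combination is worse than its control. A plain product
  $(S_c - S_{\text{combo}})(1 - \mathrm{HR})$ fails the last requirement:
  both factors flip sign together, so a *worse* combination would score
  positive. Since the two factors always share a sign, taking the HR
  factor as a magnitude preserves every value where the combination beats
  its control and fixes the sign elsewhere. The formula lives in a single
  function (`idakit.ida.idacomboscore`) so an alternative scoring rule can
  be swapped in without touching the workflows.

### Workflow conventions

- **2-drug HR control.** The focused grid reports the HR of the
  combination against the *better* monotherapy (lower mean survival) at
  the same concentrations — consistent with the IDA baseline, and making
  HR = 1 exactly when the combination adds nothing over its best
  component.
- **Batch ranking.** Batch modes run the focused code path per pair, so
  every ranking row is bit-identical to a focused recomputation. Ranking
  happens at the maximum concentration of each drug *available in the
  screen after any Csustained cap*; sort order is IDAComboscore descending
  or HR ascending, stable, with ties broken by ascending treatment label.
  The full concentration table is always retained; the top-k view
  (default k = 10) is derived from it at write time.
- **Test vs control.** Computed for arbitrary therapy pairs, but when the
  test therapy's drug set does not contain every control drug the result
  carries a non-fatal warning flag: IDA-based HRs have not been validated
  in that regime.

### Numerical choices

- Concentrations match tested doses exactly within relative tolerance
  1e-6; there is no interpolation between doses — interpolating would
  invent measurements.
- Duplicate (model, drug, concentration) rows agreeing within 1e-9
  collapse to one record; conflicting duplicates are an error, because
  silently averaging would hide upload mistakes.
- Numeric parsing uses Python's correctly-rounded float conversion so that
  write → load round-trips are bit-exact (the fast CSV float paths in
  common parsers are off by a few ulp, which would break byte-level
  reproducibility guarantees).
- Efficacies are never clipped to $[0, 1]$. Viability-like values outside
  $[-0.05, 1.05]$ trigger a validation warning, not an error; the
  negative-survival domain error downstream is the hard stop.
- Means accumulate in double precision; test comparisons use 1e-9
  absolute tolerance (1e-12 for pure algebraic identities).

## The synthetic screen generator

The generator emulates the *structure* of a pharmacogenomic viability
screen, not any particular dataset's distributions:

- **Dose response.** Each drug has a Hill curve
  $v(c) = e_\infty + (1 - e_\infty) / (1 + (c/\mathrm{EC50})^h)$ —
  monotone, $v(0) = 1$, residual viability $e_\infty$ at saturating dose.
- **Population heterogeneity.** Per mechanism of action, a fraction of
  models (default 0.5) is sensitive (base EC50); the rest have EC50
  shifted up by a fold factor (default 30×, far enough that the tested
  grid barely affects insensitive lines). Within a class, per-model EC50s
  get log-normal dispersion (default 0.25 log10 units, a standard
  pharmacological heterogeneity scale). Drugs sharing a mechanism share
  each model's class.
- **Between-mechanism overlap.** Classes across mechanisms are coupled by
  a Gaussian copula: latent standard normals with an equicorrelation
  matrix (eigendecomposition sampling, so the singular endpoints ±1 work
  exactly), thresholded at the sensitive-fraction quantile. One parameter
  sweeps from maximally complementary (−1) through independent (0) to
  redundant (+1); for $m > 2$ mechanisms positive semi-definiteness
  restricts it to $\geq -1/(m-1)$.
- **Noise.** Additive Gaussian (default SD 0.02 in the packaged default
  config, roughly the replicate noise of a well-run viability assay),
  truncated at 0 only — values slightly above 1 occur in real screens and
  deliberately keep the out-of-range warning path exercised.
- **Default study conditions.** The packaged default config is two
  single-drug mechanisms with EC50 1 µM, Hill slope 2, $e_\infty$ 0.05,
  three doses (0.1, 1, 10 µM) and 100 models — small enough to run
  everywhere, large enough that population means are stable to a few
  percent.

What passing tests on synthetic screens do **not** show: robustness to the
assay artefacts of real screens (plate effects, censored dose ranges,
missing measurements are only partially emulated), to mis-annotated
orientation flags, or to efficacy metrics with heavy-tailed error. The
generator never fits real data and makes no attempt to match CTRP/GDSC/
PRISM quantitatively.

The `make_disjoint_pair_fixture` benchmark is the analytic anchor: drug A
kills exactly half the models (viability 0.1 vs 0.9), drug B the
complement, A_copy duplicates A. Noise-free, the IDA combination A+B has
mean viability 0.1 and HR 0.2 against A alone, while A+A_copy stays at
HR 1 — hand-computable targets used in tests and the acceptance script.

## Design decisions that were genuinely open

- **Input dialect.** No standard exists for "a monotherapy screen table";
  idakit fixes a strict, documented one (exact column names, UTF-8,
  extension-based delimiter) so validation failures are precise.
- **Simulation config format.** YAML, mirroring the dataclass fields, with
  per-drug blocks; chosen over an ad-hoc key/value grammar because a
  schema with nested drug entries needs real structure.
- **Orientation flag is mandatory.** The single most dangerous silent
  error in this domain is flipping lower/higher-is-better; the CLI refuses
  to guess.
- **Errors vs flags.** Anything that would corrupt a single comparison
  (missing measurements, negative survival) raises; anything that only
  invalidates one batch row (undefined HR, no shared models) flags the row
  and excludes it from ranking.
- **Plots are out of scope.** Outputs are deterministic tab-delimited
  tables plus a key=value metadata sidecar and run manifest; graphics can
  be layered on by the caller.

## Problem sizes

The test suite and acceptance script run entirely on generated data:
random screens up to 50 models × 4 drugs (hundreds of replicates for
oracle and invariance checks), simulated screens of 80-200 models for the
overlap-benefit relationship (20 seeds per correlation level), and the
4-8-model analytic fixtures. These sizes keep every population mean well
resolved while the whole suite completes in well under a minute.

## Known limitations

- No confidence intervals or uncertainty propagation on predictions.
- No per-model weighting; every evaluable model counts equally regardless
  of cancer-type composition.
- The IDAComboscore here follows the contract above; other IDA
  implementations may scale their score differently, so cross-tool score
  comparisons should be made via HR and mean efficacies, which are
  unambiguous.
- Excel ingestion and downloaders for public screen releases are
  deliberately absent; export such data to the text dialect first.
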