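"""The three prediction workflows: 2-Drug, Control Plus One, Test vs Control.

Each workflow composes the IDA combination rule with population-level
metrics and produces deterministic tabular output:

* **2-Drug** — a single pair across user-selected concentration grids
  (focused) or one anchor drug against many candidates over all available
  concentrations (batch), ranked at the maximum available concentration of
  each drug.
* **Control Plus One** — the added benefit of one extra drug on top of a
  fixed control therapy, reporting the HR against the control *and* against
  the added drug alone (a combination can beat the control yet be no better
  than the added drug by itself).
* **Test vs Control** — one arbitrary therapy against another, as might be
  compared in a clinical trial, with a warning when the test therapy does
  not contain every control drug (the regime where IDA-based HRs are not
  validated).

Batch rankings are computed by running the focused code path per pair, so a
ranking row is always bit-identical to the focused recomputation. Ties are
broken by ascending treatment label under a stable sort, making output
order platform-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._version import __version__
from .errors import ConfigurationError, EmptySelectionError
from .ida import (
    ComboMetrics,
    Treatment,
    combo_metrics,
    hazard_ratio,
    idacomboscore,
    population_efficacy,
    predict_combo_per_model,
    survival_fraction,
)
from .screen_io import MonotherapyScreen, evaluable_models

GRID_COLUMNS = [
    "conc_a",
    "conc_b",
    "mean_efficacy_a",
    "mean_efficacy_b",
    "mean_efficacy_combo",
    "hr_vs_best_mono",
    "idacomboscore",
    "n_models",
]

#: Flag values used in batch tables; explicit beats silent.
FLAG_OK = ""
FLAG_NO_SHARED_MODELS = "no_shared_models"
FLAG_UNDEFINED_HR = "undefined_hr"


@dataclass(frozen=True)
class GridPrediction:
    """2-drug focused output: one row per requested (conc_a, conc_b) pair,
    sorted by (conc_a, conc_b)."""

    drug_a: str
    drug_b: str
    grid: pd.DataFrame = field(repr=False)
    metadata: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class PredictionTable:
    """Batch/focused tabular output plus run provenance.

    ``table`` always retains every concentration row; ``ranking`` (batch
    modes) keeps one row per pair at maximum concentrations, sorted by the
    chosen metric, with flagged pairs excluded. The top-k view is derived
    from ``ranking`` when writing, never recomputed.
    """

    table: pd.DataFrame = field(repr=False)
    ranking: pd.DataFrame | None = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict, repr=False)

    def top(self, k: int | None = None) -> pd.DataFrame:
        if self.ranking is None:
            raise ConfigurationError("this prediction table has no ranking view")
        k = self.metadata.get("top_k", 10) if k is None else k
        return self.ranking.head(k)


def _pair_metrics(
    screen: MonotherapyScreen,
    combo_mean: float,
    control_mean: float,
) -> tuple[float, float]:
    """HR and IDAComboscore of a combination vs a control, NaN when undefined."""
    hr = hazard_ratio(combo_mean, control_mean, screen.lower_is_better)
    score = idacomboscore(combo_mean, control_mean, screen.lower_is_better)
    return (np.nan if hr is None else hr, np.nan if score is None else score)


# -- 2-Drug ----------------------------------------------------------------


def two_drug_focused(
    screen: MonotherapyScreen,
    drug_a: str,
    concs_a: Sequence[float],
    drug_b: str,
    concs_b: Sequence[float],
    models: Sequence[str] | None = None,
) -> GridPrediction:
    """Predict one 2-drug combination across a concentration grid.

    For every (c_a, c_b) pair: population mean efficacy of each monotherapy
    and of the IDA-predicted combination, the HR of the combination versus
    the better monotherapy (the one with lower mean survival — the IDA
    baseline), and the IDAComboscore versus that control.

    All requested concentrations must be tested doses (exact match within
    relative tolerance; no interpolation). The model set is the intersection
    of models evaluable for every requested component, so every grid cell
    averages over the same population.
    """
    concs_a = [screen.resolve_concentration(drug_a, c) for c in concs_a]
    concs_b = [screen.resolve_concentration(drug_b, c) for c in concs_b]
    components = [(drug_a, c) for c in concs_a] + [(drug_b, c) for c in concs_b]
    if models is None:
        models = evaluable_models(screen, components)
    else:
        models = sorted(set(models) & set(evaluable_models(screen, components)))
    if len(models) == 0:
        raise EmptySelectionError(
            f"no models evaluable for every requested dose of {drug_a!r} and {drug_b!r}"
        )

    mono_a = {c: screen.monotherapy_values(drug_a, c, models) for c in sorted(set(concs_a))}
    mono_b = {c: screen.monotherapy_values(drug_b, c, models) for c in sorted(set(concs_b))}
    rows = []
    for ca in sorted(set(concs_a)):
        for cb in sorted(set(concs_b)):
            combo = predict_combo_per_model(
                screen, Treatment(components=((drug_a, ca), (drug_b, cb))), models
            )
            mean_a = population_efficacy(
                # PerModelEfficacy-free mean: plain Series mean, same accumulator
                {m: v for m, v in mono_a[ca].items()}
            )
            mean_b = population_efficacy({m: v for m, v in mono_b[cb].items()})
            mean_combo = population_efficacy(combo)
            s_a = survival_fraction(mean_a, screen.lower_is_better)
            s_b = survival_fraction(mean_b, screen.lower_is_better)
            best_mean = mean_a if s_a <= s_b else mean_b
            hr, score = _pair_metrics(screen, mean_combo, best_mean)
            rows.append((ca, cb, mean_a, mean_b, mean_combo, hr, score, len(models)))
    grid = pd.DataFrame(rows, columns=GRID_COLUMNS)
    meta = {
        "workflow": "two_drug_focused",
        "dataset": screen.name,
        "drug_a": drug_a,
        "drug_b": drug_b,
        "lower_is_better": screen.lower_is_better,
        "n_models": len(models),
        "version": __version__,
    }
    return GridPrediction(drug_a=drug_a, drug_b=drug_b, grid=grid, metadata=meta)


def _rank(table: pd.DataFrame, rank_by: str) -> pd.DataFrame:
    """Stable sort of ranking rows: IDAComboscore descending or HR ascending,
    ties broken by ascending treatment label."""
    if rank_by not in ("idacomboscore", "hr"):
        raise ConfigurationError(f"rank_by must be 'idacomboscore' or 'hr', got {rank_by!r}")
    column = "idacomboscore" if rank_by == "idacomboscore" else "hr_vs_control"
    ranked = table[table["flag"] == FLAG_OK]
    ranked = ranked.sort_values("label", kind="stable")
    ranked = ranked.sort_values(
        column, ascending=(rank_by == "hr"), kind="stable"
    )
    return ranked.reset_index(drop=True)


def two_drug_batch(
    screen: MonotherapyScreen,
    anchor_drug: str,
    candidate_drugs: Sequence[str],
    models: Sequence[str] | None = None,
    rank_by: str = "idacomboscore",
    top_k: int = 10,
) -> PredictionTable:
    """Evaluate (anchor, candidate) pairs over all available concentrations.

    The full table holds every concentration pair for every candidate. The
    ranking view keeps, per pair, the row at the maximum available
    concentration of each drug (in the possibly cap-filtered screen) and
    sorts by the chosen metric. Candidates equal to the anchor are skipped
    with a warning; candidates sharing no evaluable model with the anchor
    appear flagged in the full table and are excluded from the ranking.
    """
    if not candidate_drugs:
        raise ConfigurationError("candidate drug list is empty")
    anchor_concs = screen.concentrations(anchor_drug)
    full_parts: list[pd.DataFrame] = []
    rank_parts: list[pd.DataFrame] = []
    for candidate in candidate_drugs:
        if candidate == anchor_drug:
            warnings.warn(
                f"candidate {candidate!r} equals the anchor drug; pair skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        cand_concs = screen.concentrations(candidate)
        base = {"drug_a": anchor_drug, "drug_b": candidate}
        try:
            focused = two_drug_focused(
                screen, anchor_drug, list(anchor_concs), candidate, list(cand_concs), models
            )
        except EmptySelectionError:
            row = pd.DataFrame(
                [{**base, **{c: np.nan for c in GRID_COLUMNS},
                  "label": f"{anchor_drug} + {candidate}", "flag": FLAG_NO_SHARED_MODELS}]
            )
            full_parts.append(row)
            continue
        part = focused.grid.copy()
        part.insert(0, "drug_a", anchor_drug)
        part.insert(1, "drug_b", candidate)
        part["label"] = [
            Treatment(((anchor_drug, ca), (candidate, cb))).label
            for ca, cb in zip(part["conc_a"], part["conc_b"])
        ]
        part["flag"] = np.where(part["hr_vs_best_mono"].isna(), FLAG_UNDEFINED_HR, FLAG_OK)
        full_parts.append(part)
        at_max = part[
            (part["conc_a"] == anchor_concs.max()) & (part["conc_b"] == cand_concs.max())
        ]
        rank_parts.append(at_max)
    if not full_parts:
        raise ConfigurationError("no candidate pairs left to evaluate")
    full = pd.concat(full_parts, ignore_index=True)
    rank_rows = (
        pd.concat(rank_parts, ignore_index=True)
        if rank_parts
        else full.iloc[0:0]
    )
    rank_rows = rank_rows.rename(columns={"hr_vs_best_mono": "hr_vs_control"})
    ranking = _rank(rank_rows, rank_by)
    meta = {
        "workflow": "two_drug_batch",
        "dataset": screen.name,
        "anchor_drug": anchor_drug,
        "candidates": ",".join(candidate_drugs),
        "rank_by": rank_by,
        "top_k": top_k,
        "lower_is_better": screen.lower_is_better,
        "version": __version__,
    }
    return PredictionTable(table=full, ranking=ranking, metadata=meta)


# -- Control Plus One ------------------------------------------------------


CP1_COLUMNS = [
    "added_drug",
    "added_conc",
    "mean_efficacy_control",
    "mean_efficacy_added",
    "mean_efficacy_combo",
    "hr_vs_control",
    "hr_vs_added_drug",
    "idacomboscore",
    "n_models",
    "label",
    "flag",
]


def control_plus_one_focused(
    screen: MonotherapyScreen,
    control: Treatment,
    added_drug: str,
    added_concs: Sequence[float],
    models: Sequence[str] | None = None,
) -> PredictionTable:
    """Add one drug to a fixed control therapy across chosen concentrations.

    Per added concentration: the combination mean, HR versus the control,
    HR versus the added drug alone at that concentration, and the
    IDAComboscore versus the control. Requesting a drug already in the
    control is a configuration error — the semantics would be ambiguous.
    """
    if added_drug in control.drugs:
        raise ConfigurationError(
            f"added drug {added_drug!r} is already a component of control {control.label!r}"
        )
    added_concs = [screen.resolve_concentration(added_drug, c) for c in added_concs]
    if not added_concs:
        raise ConfigurationError("no concentrations requested for the added drug")
    components = list(control.components) + [(added_drug, c) for c in added_concs]
    if models is None:
        models = evaluable_models(screen, components)
    else:
        models = sorted(set(models) & set(evaluable_models(screen, components)))
    if len(models) == 0:
        raise EmptySelectionError(
            f"no models evaluable for control {control.label!r} plus every "
            f"requested dose of {added_drug!r}"
        )
    control_mean = population_efficacy(predict_combo_per_model(screen, control, models))
    rows = []
    for conc in sorted(set(added_concs)):
        combo = Treatment(components=(*control.components, (added_drug, conc)))
        combo_mean = population_efficacy(predict_combo_per_model(screen, combo, models))
        added_mean = population_efficacy(
            {m: v for m, v in screen.monotherapy_values(added_drug, conc, models).items()}
        )
        hr_control, score = _pair_metrics(screen, combo_mean, control_mean)
        hr_added, _ = _pair_metrics(screen, combo_mean, added_mean)
        flag = FLAG_UNDEFINED_HR if np.isnan(hr_control) else FLAG_OK
        rows.append(
            (added_drug, conc, control_mean, added_mean, combo_mean,
             hr_control, hr_added, score, len(models), combo.label, flag)
        )
    table = pd.DataFrame(rows, columns=CP1_COLUMNS)
    meta = {
        "workflow": "control_plus_one_focused",
        "dataset": screen.name,
        "control": control.label,
        "added_drug": added_drug,
        "lower_is_better": screen.lower_is_better,
        "n_models": len(models),
        "version": __version__,
    }
    return PredictionTable(table=table, ranking=None, metadata=meta)


def control_plus_one_batch(
    screen: MonotherapyScreen,
    control: Treatment,
    candidate_drugs: Sequence[str],
    models: Sequence[str] | None = None,
    rank_by: str = "idacomboscore",
    top_k: int = 10,
) -> PredictionTable:
    """Add many candidate drugs (one at a time) to a fixed control therapy.

    Each candidate is evaluated at all of its available concentrations; the
    ranking view keeps the row at each candidate's maximum available
    concentration. Candidates already in the control are skipped with a
    warning, mirroring the anchor==candidate rule of the 2-drug batch.
    """
    if not candidate_drugs:
        raise ConfigurationError("candidate drug list is empty")
    full_parts: list[pd.DataFrame] = []
    rank_parts: list[pd.DataFrame] = []
    for candidate in candidate_drugs:
        if candidate in control.drugs:
            warnings.warn(
                f"candidate {candidate!r} is already in the control therapy; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        cand_concs = screen.concentrations(candidate)
        try:
            focused = control_plus_one_focused(
                screen, control, candidate, list(cand_concs), models
            )
        except EmptySelectionError:
            row = pd.DataFrame(
                [{**{c: np.nan for c in CP1_COLUMNS},
                  "added_drug": candidate,
                  "label": f"{control.label} + {candidate}",
                  "flag": FLAG_NO_SHARED_MODELS}]
            )
            full_parts.append(row)
            continue
        part = focused.table
        full_parts.append(part)
        rank_parts.append(part[part["added_conc"] == cand_concs.max()])
    if not full_parts:
        raise ConfigurationError("no candidate drugs left to evaluate")
    full = pd.concat(full_parts, ignore_index=True)
    rank_rows = pd.concat(rank_parts, ignore_index=True) if rank_parts else full.iloc[0:0]
    ranking = _rank(rank_rows, rank_by)
    meta = {
        "workflow": "control_plus_one_batch",
        "dataset": screen.name,
        "control": control.label,
        "candidates": ",".join(candidate_drugs),
        "rank_by": rank_by,
        "top_k": top_k,
        "lower_is_better": screen.lower_is_better,
        "version": __version__,
    }
    return PredictionTable(table=full, ranking=ranking, metadata=meta)


# -- Test vs Control -------------------------------------------------------


@dataclass(frozen=True)
class TestVsControlResult:
    """A single test-vs-control comparison plus validity flags."""

    metrics: ComboMetrics
    test: Treatment
    control: Treatment
    non_superset_warning: bool

    def to_frame(self) -> pd.DataFrame:
        m = self.metrics
        return pd.DataFrame(
            [
                {
                    "test": self.test.label,
                    "control": self.control.label,
                    "mean_efficacy_test": m.mean_test,
                    "mean_efficacy_control": m.mean_control,
                    "hr_vs_control": np.nan if m.hazard_ratio is None else m.hazard_ratio,
                    "idacomboscore": np.nan if m.idacomboscore is None else m.idacomboscore,
                    "n_models": m.n_models,
                    "non_superset_warning": self.non_superset_warning,
                }
            ]
        )


def test_vs_control(
    screen: MonotherapyScreen,
    test: Treatment,
    control: Treatment,
    models: Sequence[str] | None = None,
) -> TestVsControlResult:
    """Compare an arbitrary test therapy against an arbitrary control.

    Both therapies are evaluated on the shared evaluable model set. When
    the test therapy's drug set does not contain every control drug, the
    result is still computed but carries a non-fatal warning flag: the
    IDA-based HR has not been validated for comparisons where the test
    therapy is not the control therapy plus additional drugs.
    """
    metrics = combo_metrics(screen, test, control, models)
    non_superset = not set(control.drugs).issubset(set(test.drugs))
    if non_superset:
        warnings.warn(
            f"test therapy {test.label!r} does not contain every drug of control "
            f"{control.label!r}; HR predictions are not validated when the test "
            "therapy is not the control therapy plus one or more additional drugs",
            UserWarning,
            stacklevel=2,
        )
    return TestVsControlResult(
        metrics=metrics, test=test, control=control, non_superset_warning=non_superset
    )


# -- output ----------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a prediction table as tab-delimited UTF-8 with a header row."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def write_metadata(metadata: dict, path: str | Path) -> Path:
    """Write run metadata as key=value lines (one per key, sorted)."""
    path = Path(path)
    lines = [f"{k}={metadata[k]}" for k in sorted(metadata)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
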