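"""Independent drug action (IDA): combination rule and population metrics.

IDA hypothesizes that a combination therapy's baseline efficacy in a given
model is the effect of the single best drug in the combination — no
interaction term. For a viability-like metric (lower = better drug effect)
the per-model combination efficacy is therefore the *minimum* of the
component monotherapy efficacies; for a higher-is-better metric it is the
maximum. Population-level efficacy is the unweighted arithmetic mean over
the evaluable models; predictions are population-level, never per-patient.

Two derived metrics compare a test therapy against a control therapy:

* **Hazard ratio (HR)** — the ratio of mean survival fractions,
  ``S_test / S_control``, where ``S = mean efficacy`` for a viability-like
  metric and ``S = 1 − mean efficacy`` otherwise. HR = 1 means the test
  therapy provides no benefit over the control; lower is better. HRs are
  only well defined for metrics ranging 0-1; a negative mean survival is a
  domain error rather than a silently nonsensical number.

* **IDAComboscore** — a ranking score for combinations that do not share a
  common control: ``(S_control − S_combo) × |1 − HR|``. It is strictly
  increasing in additional cell death versus the control and strictly
  decreasing in HR, is 0 when the combination matches its control, and is
  negative when the combination is worse. Higher is better. The formula is
  isolated in :func:`idacomboscore` so an alternative scoring rule can be
  swapped in without touching anything else.

This module is pure computation: no file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptySelectionError, MetricDomainError
from .screen_io import MonotherapyScreen, evaluable_models


@dataclass(frozen=True)
class Treatment:
    """An ordered set of (drug, concentration) components.

    A treatment holds one or more drugs, each at a single concentration.
    Duplicate (drug, concentration) pairs are collapsed on construction, so
    combining a drug with itself at the same dose is the monotherapy.
    """

    components: tuple[tuple[str, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigurationError("a treatment needs at least one (drug, concentration) component")
        seen: list[tuple[str, float]] = []
        for drug, conc in self.components:
            conc = float(conc)
            if not np.isfinite(conc) or conc < 0:
                raise ConfigurationError(
                    f"component {drug}@{conc!r}: concentration must be finite and >= 0"
                )
            if (drug, conc) not in seen:
                seen.append((drug, conc))
        object.__setattr__(self, "components", tuple(seen))
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        return " + ".join(f"{d}@{c:g}" for d, c in self.components)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.components)

    @classmethod
    def from_spec(cls, spec: str, label: str = "") -> "Treatment":
        """Parse ``"drugA@1.0,drugB@2.5"`` into a Treatment."""
        components = []
        for token in spec.split(","):
            token = token.strip()
            if not token:
                continue
            drug, sep, conc = token.rpartition("@")
            if not sep or not drug.strip():
                raise ConfigurationError(
                    f"malformed treatment token {token!r}; expected drug@concentration"
                )
            try:
                conc_val = float(conc)
            except ValueError:
                raise ConfigurationError(
                    f"malformed treatment token {token!r}: concentration {conc!r} is not a number"
                ) from None
            components.append((drug.strip(), conc_val))
        if not components:
            raise ConfigurationError(f"treatment spec {spec!r} contains no components")
        return cls(components=tuple(components), label=label)


@dataclass(frozen=True)
class PerModelEfficacy:
    """Per-model predicted (or measured) efficacy under one treatment."""

    values: pd.Series = field(repr=False)  # index: model_id
    lower_is_better: bool

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise EmptySelectionError("per-model efficacy over zero models")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise MetricDomainError("per-model efficacies must be finite")


@dataclass(frozen=True)
class ComboMetrics:
    """One test-vs-control comparison: means, HR, IDAComboscore, model count.

    ``hazard_ratio`` and ``idacomboscore`` are ``None`` when undefined
    (control survival exactly 0) — reported explicitly, never dropped.
    """

    mean_test: float
    mean_control: float
    hazard_ratio: float | None
    idacomboscore: float | None
    n_models: int

    def __post_init__(self) -> None:
        if self.n_models <= 0:
            raise EmptySelectionError("combo metrics over zero models")
        if self.hazard_ratio is not None and self.hazard_ratio < 0:
            raise MetricDomainError(f"hazard ratio must be >= 0, got {self.hazard_ratio}")


def predict_combo_per_model(
    screen: MonotherapyScreen,
    treatment: Treatment,
    models: Sequence[str],
) -> PerModelEfficacy:
    """Per-model IDA prediction: the best single-component efficacy.

    Elementwise minimum over component monotherapy vectors when lower is
    better, maximum otherwise. Single-component treatments return the
    monotherapy values unchanged. Every model must carry a measurement for
    every component (use :func:`idakit.screen_io.evaluable_models` first);
    a gap raises :class:`idakit.errors.CoverageError`.
    """
    if len(models) == 0:
        raise EmptySelectionError("prediction requested over zero models")
    columns = {
        f"{drug}@{conc}": screen.monotherapy_values(drug, conc, models)
        for drug, conc in treatment.components
    }
    mat = pd.DataFrame(columns)
    best = mat.min(axis=1) if screen.lower_is_better else mat.max(axis=1)
    return PerModelEfficacy(values=best, lower_is_better=screen.lower_is_better)


def population_efficacy(per_model: PerModelEfficacy | Mapping[str, float]) -> float:
    """Unweighted arithmetic mean efficacy across models."""
    values = per_model.values if isinstance(per_model, PerModelEfficacy) else pd.Series(per_model)
    if len(values) == 0:
        raise EmptySelectionError("population efficacy over zero models")
    return float(np.mean(values.to_numpy(dtype=float)))


def survival_fraction(mean_efficacy: float, lower_is_better: bool) -> float:
    """Mean fraction of model systems surviving treatment.

    For a viability-like metric survival *is* the efficacy value; for a
    higher-is-better metric it is 1 − efficacy.
    """
    return float(mean_efficacy) if lower_is_better else 1.0 - float(mean_efficacy)


def hazard_ratio(
    mean_test: float, mean_control: float, lower_is_better: bool
) -> float | None:
    """HR of a test therapy versus a control: S_test / S_control.

    Returns ``None`` (undefined) when control survival is exactly 0 rather
    than infinity, keeping batch tables machine-readable. Negative survival
    on either side raises :class:`MetricDomainError` — that situation means
    the efficacy metric left [0, 1] and HRs are no longer meaningful.
    """
    s_test = survival_fraction(mean_test, lower_is_better)
    s_control = survival_fraction(mean_control, lower_is_better)
    if s_test < 0 or s_control < 0:
        raise MetricDomainError(
            f"negative mean survival (test={s_test:.6g}, control={s_control:.6g}); "
            "hazard ratios are only well defined for efficacy metrics in [0, 1]"
        )
    if s_control == 0:
        return None
    return s_test / s_control


def idacomboscore(
    mean_combo: float, mean_control: float, lower_is_better: bool
) -> float | None:
    """IDAComboscore of a combination versus its control.

    ``(S_control − S_combo) × |1 − HR|``: rewards additional cell death
    over the control while penalizing high HR; 0 when the combination
    matches its control, negative when it is worse, higher = better.
    The HR factor enters as a magnitude so that a combination worse than
    its control always scores negative (added death and ``1 − HR`` share
    their sign, so a plain product would turn two penalties into a
    reward). Propagates an undefined HR as an undefined score (``None``).
    """
    hr = hazard_ratio(mean_combo, mean_control, lower_is_better)
    if hr is None:
        return None
    s_combo = survival_fraction(mean_combo, lower_is_better)
    s_control = survival_fraction(mean_control, lower_is_better)
    return (s_control - s_combo) * abs(1.0 - hr)


def combo_metrics(
    screen: MonotherapyScreen,
    test: Treatment,
    control: Treatment,
    models: Sequence[str] | None = None,
) -> ComboMetrics:
    """Full test-vs-control comparison on a shared evaluable model set.

    When ``models`` is None, uses the intersection of the models evaluable
    for the test and for the control treatments. Both treatments are always
    evaluated on the same model set.
    """
    if models is None:
        models = sorted(
            set(evaluable_models(screen, test.components))
            & set(evaluable_models(screen, control.components))
        )
    if len(models) == 0:
        raise EmptySelectionError(
            f"no models evaluable for both {test.label!r} and {control.label!r}"
        )
    mean_test = population_efficacy(predict_combo_per_model(screen, test, models))
    mean_control = population_efficacy(predict_combo_per_model(screen, control, models))
    hr = hazard_ratio(mean_test, mean_control, screen.lower_is_better)
    score = idacomboscore(mean_test, mean_control, screen.lower_is_better)
    return ComboMetrics(
        mean_test=mean_test,
        mean_control=mean_control,
        hazard_ratio=hr,
        idacomboscore=score,
        n_models=len(models),
    )
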