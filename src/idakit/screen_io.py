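"""Reading, validating, filtering and writing monotherapy screen tables.

A *monotherapy screen* is a tidy table of single-drug, single-concentration
efficacy measurements across a panel of cell lines (models):

    model_id  drug  concentration  efficacy  [cancer_type]

Concentrations are micromolar. The efficacy column can be any per-model
measure of drug effect; for viability-like metrics (0 = all cells died,
1 = all cells alive relative to untreated control) the screen is flagged
``lower_is_better=True``. The orientation flag is deliberately explicit
everywhere: silently assuming it would flip the meaning of every hazard
ratio downstream.

Dialect: tab- or comma-delimited, autodetected from the file extension
(``.tsv``/``.txt`` = tab, ``.csv`` = comma), UTF-8, ``.`` decimal, header
row with exact column names. Identifiers are case-sensitive and
whitespace-trimmed on load. Concentrations are matched exactly (relative
tolerance 1e-6); the package never interpolates between tested doses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    EmptySelectionError,
    ScreenFormatError,
    ScreenLookupError,
    ScreenValidationError,
    ScreenValidationWarning,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("model_id", "drug", "concentration", "efficacy")
OPTIONAL_COLUMNS = ("cancer_type",)

#: Relative tolerance for matching a requested concentration against tested
#: doses. No interpolation is ever performed between doses.
CONC_RTOL = 1e-6

#: Duplicate (model, drug, concentration) triples whose efficacies agree
#: within this absolute tolerance are collapsed; larger spreads are an error.
DUPLICATE_ATOL = 1e-9


def concentrations_match(values: np.ndarray, target: float, rtol: float = CONC_RTOL) -> np.ndarray:
    """Boolean mask of ``values`` equal to ``target`` within relative tolerance.

    Zero only matches zero exactly (a relative tolerance around zero would
    match nothing else anyway).
    """
    values = np.asarray(values, dtype=float)
    return np.abs(values - target) <= rtol * np.maximum(np.abs(values), abs(target))


@dataclass(frozen=True)
class MonotherapyScreen:
    """An immutable monotherapy screen.

    Parameters
    ----------
    data:
        Tidy DataFrame with columns ``model_id``, ``drug``, ``concentration``,
        ``efficacy`` and optionally ``cancer_type``.
    lower_is_better:
        True when lower efficacy values indicate a stronger drug effect
        (viability-like metrics). Determines which hazard-ratio formula
        applies downstream.
    name:
        Dataset label carried into output metadata.
    """

    data: pd.DataFrame = field(repr=False)
    lower_is_better: bool
    name: str = "screen"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ScreenFormatError(f"screen data is missing required column(s): {', '.join(missing)}")
        if len(self.data) == 0:
            raise ScreenValidationError("screen contains no records")
        conc = self.data["concentration"].to_numpy(dtype=float)
        if not np.all(np.isfinite(conc)) or np.any(conc < 0):
            raise ScreenValidationError("concentrations must be finite and >= 0")
        eff = self.data["efficacy"].to_numpy(dtype=float)
        if not np.all(np.isfinite(eff)):
            raise ScreenValidationError("efficacy values must be finite")
        dup = self.data.duplicated(subset=["model_id", "drug", "concentration"])
        if dup.any():
            offenders = self.data.loc[dup, ["model_id", "drug", "concentration"]]
            raise ScreenValidationError(
                f"duplicate (model_id, drug, concentration) triples remain after loading: "
                f"{offenders.to_records(index=False).tolist()[:5]}"
            )
        if self.lower_is_better:
            out = (eff < -0.05) | (eff > 1.05)
            if out.any():
                warnings.warn(
                    f"{int(out.sum())} efficacy value(s) outside [-0.05, 1.05] in a "
                    "lower-is-better (viability-like) screen; hazard ratios are only "
                    "well defined for metrics in [0, 1]",
                    ScreenValidationWarning,
                    stacklevel=2,
                )

    # -- introspection -----------------------------------------------------

    @property
    def models(self) -> list[str]:
        return sorted(self.data["model_id"].unique())

    @property
    def drugs(self) -> list[str]:
        return sorted(self.data["drug"].unique())

    @property
    def has_cancer_type(self) -> bool:
        return "cancer_type" in self.data.columns

    def concentrations(self, drug: str) -> np.ndarray:
        """Sorted unique tested concentrations for ``drug``."""
        sub = self.data.loc[self.data["drug"] == drug, "concentration"]
        if len(sub) == 0:
            raise ScreenLookupError(f"drug {drug!r} is not present in screen {self.name!r}")
        return np.sort(sub.unique())

    def max_concentration(self, drug: str) -> float:
        return float(self.concentrations(drug)[-1])

    def resolve_concentration(self, drug: str, concentration: float) -> float:
        """Map a requested concentration onto the tested dose it matches.

        Raises :class:`ScreenLookupError` when no tested dose matches within
        the relative tolerance — the package refuses to interpolate.
        """
        tested = self.concentrations(drug)
        mask = concentrations_match(tested, float(concentration))
        if not mask.any():
            raise ScreenLookupError(
                f"concentration {concentration!r} of drug {drug!r} is not a tested dose "
                f"in screen {self.name!r} (tested: {tested.tolist()})"
            )
        return float(tested[np.argmax(mask)])

    def monotherapy_values(
        self, drug: str, concentration: float, models: Sequence[str]
    ) -> pd.Series:
        """Per-model efficacy of ``drug`` at ``concentration`` for ``models``.

        Every requested model must carry a measurement; a gap raises
        :class:`CoverageError` naming the model and component.
        """
        conc = self.resolve_concentration(drug, concentration)
        sub = self.data[
            (self.data["drug"] == drug)
            & concentrations_match(self.data["concentration"].to_numpy(), conc)
        ]
        series = sub.set_index("model_id")["efficacy"]
        missing = [m for m in models if m not in series.index]
        if missing:
            raise CoverageError(
                f"model(s) {missing[:5]} lack a measurement for component "
                f"{drug}@{conc} in screen {self.name!r}"
            )
        return series.reindex(list(models)).astype(float)

    def equals(self, other: "MonotherapyScreen") -> bool:
        """Equality on record set (order-insensitive) and orientation flag."""
        if self.lower_is_better != other.lower_is_better:
            return False
        cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in self.data.columns]
        if set(cols) != {c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in other.data.columns}:
            return False
        key = ["model_id", "drug", "concentration"]
        a = self.data[cols].sort_values(key).reset_index(drop=True)
        b = other.data[cols].sort_values(key).reset_index(drop=True)
        return a.equals(b)


# -- loading ---------------------------------------------------------------


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_screen(
    path: str | Path,
    lower_is_better: bool,
    *,
    sep: str | None = None,
    name: str | None = None,
) -> MonotherapyScreen:
    """Load and validate a monotherapy screen from a delimited text file.

    Rows whose concentration or efficacy fail numeric coercion (or carry a
    negative concentration) are rejected with their file line numbers in a
    :class:`ScreenValidationWarning`. Duplicate (model, drug, concentration)
    triples agreeing within 1e-9 collapse to one record; conflicting
    duplicates raise :class:`ScreenValidationError` — silent averaging would
    hide upload mistakes.
    """
    path = Path(path)
    if not path.exists():
        raise ScreenFormatError(f"screen file does not exist: {path}")
    try:
        raw = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ScreenFormatError(f"screen file is empty: {path}") from None
    raw.columns = [str(c).strip() for c in raw.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ScreenFormatError(
            f"screen file {path} is missing required column(s): {', '.join(missing)} "
            f"(found: {', '.join(raw.columns)})"
        )
    if len(raw) == 0:
        raise ScreenFormatError(f"screen file has a header but no data rows: {path}")

    df = raw.copy()
    for col in ("model_id", "drug"):
        df[col] = df[col].astype(str).str.strip()
    if "cancer_type" in df.columns:
        df["cancer_type"] = df["cancer_type"].astype(str).str.strip()
    df["concentration"] = _coerce_float(df["concentration"])
    df["efficacy"] = _coerce_float(df["efficacy"])

    bad = df["concentration"].isna() | df["efficacy"].isna() | (df["concentration"] < 0)
    if bad.any():
        # +2: header occupies line 1 and pandas indices are 0-based.
        lines = (df.index[bad] + 2).tolist()
        warnings.warn(
            f"rejected {int(bad.sum())} row(s) failing type coercion or with negative "
            f"concentration at line(s) {lines[:20]} of {path.name}",
            ScreenValidationWarning,
            stacklevel=2,
        )
        df = df[~bad]
    if len(df) == 0:
        raise ScreenFormatError(f"no valid data rows remain in {path}")

    df = _collapse_duplicates(df, context=str(path))
    cols = list(REQUIRED_COLUMNS) + (["cancer_type"] if "cancer_type" in df.columns else [])
    screen = MonotherapyScreen(
        data=df[cols].reset_index(drop=True),
        lower_is_better=lower_is_better,
        name=name if name is not None else path.stem,
    )
    n_conc = screen.data.groupby("drug")["concentration"].nunique()
    logger.info(
        "loaded screen %s: %d models, %d drugs, %d-%d concentrations per drug, %d records",
        screen.name, len(screen.models), len(screen.drugs),
        int(n_conc.min()), int(n_conc.max()), len(screen.data),
    )
    return screen


def _coerce_float(series: pd.Series) -> pd.Series:
    """Coerce strings to float with Python's correctly-rounded parser so
    written values round-trip bit-exactly; unparseable or non-finite entries
    become NaN (and are rejected by the caller)."""

    def conv(x):
        try:
            v = float(str(x).strip())
        except (TypeError, ValueError):
            return np.nan
        return v if np.isfinite(v) else np.nan

    return series.map(conv).astype(float)


def _collapse_duplicates(df: pd.DataFrame, context: str) -> pd.DataFrame:
    key = ["model_id", "drug", "concentration"]
    grouped = df.groupby(key)["efficacy"]
    spread = grouped.max() - grouped.min()
    conflicts = spread[spread > DUPLICATE_ATOL]
    if len(conflicts):
        raise ScreenValidationError(
            f"duplicate (model_id, drug, concentration) triples with conflicting "
            f"efficacy values in {context}: {conflicts.index.tolist()[:5]}"
        )
    return df.drop_duplicates(subset=key, keep="first")


def write_screen(screen: MonotherapyScreen, path: str | Path) -> Path:
    """Write a screen in the package dialect (tab- or comma-delimited by
    extension, UTF-8, header row). Round-trips through :func:`load_screen`."""
    path = Path(path)
    sep = _detect_sep(path, None)
    cols = list(REQUIRED_COLUMNS) + (["cancer_type"] if screen.has_cancer_type else [])
    screen.data[cols].to_csv(path, sep=sep, index=False, encoding="utf-8")
    return path


# -- filtering -------------------------------------------------------------


def filter_models(
    screen: MonotherapyScreen,
    cancer_type: str | None = None,
    model_ids: Iterable[str] | None = None,
) -> MonotherapyScreen:
    """Restrict a screen to models matching a cancer type and/or an explicit
    id list; giving both intersects the criteria. Idempotent."""
    if cancer_type is None and model_ids is None:
        return screen
    keep = pd.Series(True, index=screen.data.index)
    if cancer_type is not None:
        if not screen.has_cancer_type:
            raise ScreenFormatError(
                f"screen {screen.name!r} carries no cancer_type annotations; "
                "cannot filter by cancer type"
            )
        keep &= screen.data["cancer_type"] == cancer_type
    if model_ids is not None:
        wanted = {str(m).strip() for m in model_ids}
        keep &= screen.data["model_id"].isin(wanted)
    sub = screen.data[keep]
    if len(sub) == 0 or sub["model_id"].nunique() == 0:
        raise EmptySelectionError(
            f"model filter (cancer_type={cancer_type!r}, model_ids={'given' if model_ids is not None else None}) "
            f"selected zero models in screen {screen.name!r}"
        )
    return replace(screen, data=sub.reset_index(drop=True))


def evaluable_models(
    screen: MonotherapyScreen, components: Sequence[tuple[str, float]]
) -> list[str]:
    """Models holding a measurement for *every* (drug, concentration)
    component, in deterministic sorted order.

    Predictions average only over these models, so every component must be
    measured in each of them.
    """
    result: set[str] | None = None
    for drug, conc in components:
        resolved = screen.resolve_concentration(drug, conc)
        sub = screen.data[
            (screen.data["drug"] == drug)
            & concentrations_match(screen.data["concentration"].to_numpy(), resolved)
        ]
        have = set(sub["model_id"])
        result = have if result is None else (result & have)
    return sorted(result or ())


# -- concentration caps ----------------------------------------------------


@dataclass(frozen=True)
class ConcentrationCapTable:
    """Per-drug maximum allowed concentration (clinically sustainable dose,
    Csustained, micromolar)."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        for drug, cap in self.entries.items():
            if not np.isfinite(cap) or cap <= 0:
                raise ScreenValidationError(
                    f"concentration cap for drug {drug!r} must be positive and finite, got {cap!r}"
                )


def load_caps(path: str | Path, *, sep: str | None = None) -> ConcentrationCapTable:
    """Load a two-column (drug, max_concentration) cap table."""
    path = Path(path)
    if not path.exists():
        raise ScreenFormatError(f"cap file does not exist: {path}")
    try:
        raw = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ScreenFormatError(f"cap file is empty: {path}") from None
    raw.columns = [str(c).strip() for c in raw.columns]
    missing = [c for c in ("drug", "max_concentration") if c not in raw.columns]
    if missing:
        raise ScreenFormatError(
            f"cap file {path} is missing required column(s): {', '.join(missing)}"
        )
    caps: dict[str, float] = {}
    for i, row in raw.iterrows():
        drug = str(row["drug"]).strip()
        try:
            cap = float(str(row["max_concentration"]).strip())
        except ValueError:
            raise ScreenFormatError(
                f"non-numeric cap {row['max_concentration']!r} for drug {drug!r} "
                f"at line {i + 2} of {path.name}"
            ) from None
        caps[drug] = cap
    return ConcentrationCapTable(entries=caps)


def apply_caps(screen: MonotherapyScreen, caps: ConcentrationCapTable) -> MonotherapyScreen:
    """Drop records above each capped drug's maximum sustainable concentration.

    Uncapped drugs pass through unchanged; caps naming drugs absent from the
    screen are a warning, not an error.
    """
    if not caps.entries:
        return screen
    present = set(screen.data["drug"].unique())
    unused = sorted(set(caps.entries) - present)
    if unused:
        warnings.warn(
            f"cap(s) for drug(s) not in screen {screen.name!r}: {unused}",
            ScreenValidationWarning,
            stacklevel=2,
        )
    keep = pd.Series(True, index=screen.data.index)
    for drug, cap in caps.entries.items():
        if drug not in present:
            continue
        conc = screen.data["concentration"].to_numpy(dtype=float)
        over = (screen.data["drug"] == drug) & (conc > cap * (1 + CONC_RTOL))
        keep &= ~over
    sub = screen.data[keep]
    if len(sub) == 0:
        raise EmptySelectionError(
            f"applying concentration caps removed every record from screen {screen.name!r}"
        )
    return replace(screen, data=sub.reset_index(drop=True))
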