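"""Synthetic monotherapy screens with known ground truth.

Real high-throughput screens (CTRP/GDSC/PRISM-style) measure the viability
of hundreds of cell lines under single drugs at a handful of doses. This
module emulates that structure so every workflow is testable without
external downloads:

* each drug follows a four-parameter-free Hill dose-response curve
  ``v(c) = e_inf + (1 − e_inf) / (1 + (c / EC50)^h)`` — monotone
  non-increasing in concentration, 1 at zero dose, ``e_inf`` residual
  viability at infinite dose;
* the cell-line population is heterogeneous: for each mechanism of action a
  configurable fraction of models is *sensitive* (base EC50) while the rest
  are *insensitive* (EC50 shifted up by a fold factor); drugs sharing a
  mechanism share each model's sensitivity class;
* sensitivity classes across mechanisms are coupled through a Gaussian
  copula on latent variables, so a single correlation parameter in [−1, 1]
  sweeps from maximally complementary (−1: drugs kill disjoint
  subpopulations) through independent (0) to fully redundant (+1) — the
  axis along which independent drug action predicts combination benefit;
* within a sensitivity class, per-model EC50s get log-normal dispersion
  (default 0.25 log10 units), the standard pharmacological heterogeneity
  shape;
* measurement noise is additive Gaussian, truncated below at 0 only —
  viability slightly above 1 occurs in real screens and keeps the
  negative-survival guard exercisable downstream.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri

from .errors import ConfigurationError, ScreenFormatError
from .screen_io import MonotherapyScreen, write_screen  # noqa: F401  (write_screen re-exported)

#: Default log10 EC50 dispersion within a sensitivity class.
DEFAULT_EC50_LOG10_SD = 0.25
#: Default fold increase of EC50 for insensitive models.
DEFAULT_EC50_SHIFT = 30.0


@dataclass(frozen=True)
class HillParams:
    """Hill dose-response parameters: EC50 (µM), slope, residual viability."""

    ec50: float
    hill_slope: float = 1.0
    e_inf: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ec50) and self.ec50 > 0):
            raise ConfigurationError(f"ec50 must be positive and finite, got {self.ec50!r}")
        if not (np.isfinite(self.hill_slope) and self.hill_slope > 0):
            raise ConfigurationError(f"hill_slope must be positive, got {self.hill_slope!r}")
        if not (0.0 <= self.e_inf <= 1.0):
            raise ConfigurationError(f"e_inf must be in [0, 1], got {self.e_inf!r}")

    def viability(self, concentration: np.ndarray | float) -> np.ndarray | float:
        """Noise-free viability at the given concentration(s); 1 at c = 0."""
        c = np.asarray(concentration, dtype=float)
        v = self.e_inf + (1.0 - self.e_inf) / (1.0 + (c / self.ec50) ** self.hill_slope)
        return float(v) if np.isscalar(concentration) else v


@dataclass(frozen=True)
class DrugSpec:
    """One simulated drug: name, mechanism class, dose grid, base curve."""

    name: str
    mechanism: str
    concentrations: tuple[float, ...]
    hill: HillParams

    def __post_init__(self) -> None:
        concs = tuple(float(c) for c in self.concentrations)
        if not concs:
            raise ConfigurationError(f"drug {self.name!r}: concentration grid is empty")
        if any((not np.isfinite(c)) or c <= 0 for c in concs):
            raise ConfigurationError(
                f"drug {self.name!r}: concentrations must be strictly positive and finite"
            )
        if list(concs) != sorted(concs):
            raise ConfigurationError(f"drug {self.name!r}: concentrations must be sorted ascending")
        object.__setattr__(self, "concentrations", concs)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic screen generator.

    ``correlation`` couples sensitivity classes between mechanisms:
    ``"independent"`` or a number in [−1, 1] (for more than two mechanisms
    the equicorrelation matrix must stay positive semi-definite, i.e.
    correlation ≥ −1/(n_mechanisms − 1)).
    """

    n_models: int
    drugs: tuple[DrugSpec, ...]
    sensitive_fraction: float = 0.5
    ec50_shift: float = DEFAULT_EC50_SHIFT
    correlation: float | str = "independent"
    noise_sd: float = 0.0
    seed: int = 0
    cancer_types: tuple[str, ...] | None = None
    ec50_log10_sd: float = DEFAULT_EC50_LOG10_SD
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_models <= 0:
            raise ConfigurationError(f"n_models must be positive, got {self.n_models}")
        if not self.drugs:
            raise ConfigurationError("at least one drug is required")
        if not (0.0 <= self.sensitive_fraction <= 1.0):
            raise ConfigurationError(
                f"sensitive_fraction must be in [0, 1], got {self.sensitive_fraction}"
            )
        if self.ec50_shift < 1.0 or not np.isfinite(self.ec50_shift):
            raise ConfigurationError(f"ec50_shift must be >= 1, got {self.ec50_shift}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        rho = self.resolved_correlation()
        n_mech = len({d.mechanism for d in self.drugs})
        lower = -1.0 if n_mech <= 1 else max(-1.0, -1.0 / (n_mech - 1))
        if not (lower - 1e-12 <= rho <= 1.0):
            raise ConfigurationError(
                f"correlation {rho} outside the valid range [{lower:g}, 1] "
                f"for {n_mech} mechanism(s)"
            )

    def resolved_correlation(self) -> float:
        if isinstance(self.correlation, str):
            if self.correlation != "independent":
                raise ConfigurationError(
                    f"correlation must be a number in [-1, 1] or 'independent', "
                    f"got {self.correlation!r}"
                )
            return 0.0
        rho = float(self.correlation)
        if not np.isfinite(rho) or not (-1.0 <= rho <= 1.0):
            raise ConfigurationError(f"correlation must be in [-1, 1], got {self.correlation!r}")
        return rho


def default_config(
    n_models: int = 100,
    seed: int = 0,
    correlation: float | str = "independent",
    noise_sd: float = 0.02,
) -> SimConfig:
    """A small two-mechanism screen: two cytotoxic drug classes, 3-dose
    half-log grids spanning the base EC50, half the population sensitive to
    each class."""
    drugs = (
        DrugSpec("drugA", "mechanism1", (0.1, 1.0, 10.0), HillParams(1.0, 2.0, 0.05)),
        DrugSpec("drugB", "mechanism2", (0.1, 1.0, 10.0), HillParams(1.0, 2.0, 0.05)),
    )
    return SimConfig(
        n_models=n_models,
        drugs=drugs,
        correlation=correlation,
        noise_sd=noise_sd,
        seed=seed,
    )


def _correlated_latents(rng: np.random.Generator, n: int, mechanisms: Sequence[str], rho: float) -> pd.DataFrame:
    """n × n_mech standard-normal latents with pairwise correlation rho.

    Sampled through the eigendecomposition of the equicorrelation matrix so
    the singular endpoints rho = ±1 work exactly.
    """
    m = len(mechanisms)
    corr = np.full((m, m), rho, dtype=float)
    np.fill_diagonal(corr, 1.0)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    transform = v @ np.diag(np.sqrt(w))
    z = rng.standard_normal(size=(n, m)) @ transform.T
    return pd.DataFrame(z, columns=list(mechanisms))


def simulate_screen(config: SimConfig) -> MonotherapyScreen:
    """Generate a monotherapy viability screen from a :class:`SimConfig`.

    Deterministic given the seed. Viability = per-model Hill curve value +
    Gaussian noise, truncated below at 0; orientation is lower-is-better.
    """
    rng = np.random.default_rng(config.seed)
    models = [f"M{i + 1:04d}" for i in range(config.n_models)]
    mechanisms = sorted({d.mechanism for d in config.drugs})
    rho = config.resolved_correlation()

    latents = _correlated_latents(rng, config.n_models, mechanisms, rho)
    # Sensitive iff the latent falls below the sensitive-fraction quantile;
    # shared latents make same-mechanism drugs agree per model.
    threshold = ndtri(config.sensitive_fraction) if 0 < config.sensitive_fraction < 1 else None
    records = []
    cancer = None
    if config.cancer_types:
        cancer = [config.cancer_types[i % len(config.cancer_types)] for i in range(config.n_models)]
    for drug in config.drugs:
        z = latents[drug.mechanism].to_numpy()
        if config.sensitive_fraction >= 1.0:
            sensitive = np.ones(config.n_models, dtype=bool)
        elif config.sensitive_fraction <= 0.0:
            sensitive = np.zeros(config.n_models, dtype=bool)
        else:
            sensitive = z < threshold
        log10_disp = rng.normal(0.0, config.ec50_log10_sd, size=config.n_models)
        ec50 = drug.hill.ec50 * np.where(sensitive, 1.0, config.ec50_shift) * 10.0 ** log10_disp
        concs = np.asarray(drug.concentrations)
        # model × dose viability surface from each model's own Hill curve
        frac = 1.0 / (1.0 + (concs[None, :] / ec50[:, None]) ** drug.hill.hill_slope)
        viability = drug.hill.e_inf + (1.0 - drug.hill.e_inf) * frac
        if config.noise_sd > 0:
            viability = viability + rng.normal(0.0, config.noise_sd, size=viability.shape)
        viability = np.maximum(viability, 0.0)
        for j, conc in enumerate(concs):
            for i, model in enumerate(models):
                rec = {
                    "model_id": model,
                    "drug": drug.name,
                    "concentration": float(conc),
                    "efficacy": float(viability[i, j]),
                }
                if cancer is not None:
                    rec["cancer_type"] = cancer[i]
                records.append(rec)
    data = pd.DataFrame.from_records(records)
    return MonotherapyScreen(data=data, lower_is_better=True, name=config.name)


def make_disjoint_pair_fixture(
    n_models: int, seed: int = 0, noise_sd: float = 0.0
) -> MonotherapyScreen:
    """The maximally complementary / maximally redundant benchmark screen.

    Three drugs at one shared concentration (1 µM): drug A kills exactly the
    first half of the models (viability 0.1, others 0.9 before noise),
    drug B kills exactly the complement, and A_copy is identical to A. The
    A+B combination therefore reaches mean viability 0.1 under independent
    drug action while A+A_copy stays at A's own 0.5 — the two ends of the
    population-overlap spectrum with hand-computable means and HRs.
    """
    if n_models <= 0 or n_models % 2 != 0:
        raise ConfigurationError(f"n_models must be positive and even, got {n_models}")
    rng = np.random.default_rng(seed)
    models = [f"M{i + 1:04d}" for i in range(n_models)]
    half = n_models // 2
    a = np.where(np.arange(n_models) < half, 0.1, 0.9)
    b = np.where(np.arange(n_models) < half, 0.9, 0.1)
    records = []
    for drug, values in (("A", a), ("B", b), ("A_copy", a)):
        noisy = values + (rng.normal(0.0, noise_sd, size=n_models) if noise_sd > 0 else 0.0)
        noisy = np.maximum(noisy, 0.0)
        for model, v in zip(models, noisy):
            records.append(
                {"model_id": model, "drug": drug, "concentration": 1.0, "efficacy": float(v)}
            )
    return MonotherapyScreen(
        data=pd.DataFrame.from_records(records),
        lower_is_better=True,
        name="disjoint_pair_fixture",
    )


# -- config file -----------------------------------------------------------


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a :class:`SimConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; each entry of ``drugs``
    holds ``name``, ``mechanism``, ``concentrations`` and a ``hill`` block
    (``ec50``, ``hill_slope``, ``e_inf``).
    """
    path = Path(path)
    if not path.exists():
        raise ScreenFormatError(f"simulation config does not exist: {path}")
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse simulation config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"simulation config {path} must be a mapping")
    try:
        drugs = tuple(
            DrugSpec(
                name=d["name"],
                mechanism=d.get("mechanism", d["name"]),
                concentrations=tuple(d["concentrations"]),
                hill=HillParams(**d.get("hill", {"ec50": 1.0})),
            )
            for d in raw.get("drugs", [])
        )
        kwargs = {k: v for k, v in raw.items() if k != "drugs"}
        if "cancer_types" in kwargs and kwargs["cancer_types"] is not None:
            kwargs["cancer_types"] = tuple(kwargs["cancer_types"])
        return SimConfig(drugs=drugs, **kwargs)
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid simulation config {path}: {exc}") from exc
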