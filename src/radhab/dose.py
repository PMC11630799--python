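"""Irradiation scenarios, weighted dose rates, and radiolytic production.

Deep fracture fluids accumulate radiation dose from in-rock decay of
long-lived radionuclides (238U, 232Th, 40K).  Absorbed dose is measured in
gray (Gy = J/kg); a biologically *weighted* dose rate (Gy-equivalent/yr)
multiplies the absorbed rate by per-particle weighting factors, because
densely ionising alpha particles do far more biological damage per gray
than gamma rays.  The same decay energy splits pore water (radiolysis),
producing H2, H2O2 and OH radicals (and, secondarily, O2) at rates set by
G-values — molecules formed per 100 eV of absorbed energy.

Dose rates are scenario *inputs* here: the two reference rates for the
Witwatersrand Basin brine system (0.02 Gy/yr for 1 ug/g U host rock,
0.3 Gy/yr for 100 ug/g U) are shipped as named presets, and a generic
linear inventory->dose helper is provided for user-supplied per-ppm
coefficients.  It makes no claim to reproduce any site-specific,
geometry-dependent derivation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "RadionuclideInventory",
    "ParticleMix",
    "ParticleWeights",
    "DoseScenario",
    "RadiolyticYield",
    "DEFAULT_WEIGHTS",
    "WEST_RAND_LOW_RATE_GY_PER_YR",
    "VAAL_REEF_HIGH_RATE_GY_PER_YR",
    "PRESET_RATES",
    "reference_scenarios",
    "effective_dose_rate",
    "accumulated_dose",
    "dose_rate_from_inventory",
    "production_rate",
    "load_gvalues",
    "load_scenario",
]

#: eV per joule and Avogadro's number, used by the G-value production model.
EV_PER_JOULE = 6.241509074e18
AVOGADRO = 6.02214076e23

PARTICLES = ("alpha", "beta", "gamma")

#: Reference absorbed dose rates for the two host-rock uranium scenarios
#: (1 ug/g U in West Rand quartzite; 100 ug/g U in the uranium-enriched
#: Vaal Reef).  The ppm->rate mapping is site specific and non-linear, so
#: these ship as opaque presets rather than derived quantities.
WEST_RAND_LOW_RATE_GY_PER_YR = 0.02
VAAL_REEF_HIGH_RATE_GY_PER_YR = 0.3

PRESET_RATES: dict[str, float] = {
    "west_rand_low": WEST_RAND_LOW_RATE_GY_PER_YR,
    "vaal_reef_high": VAAL_REEF_HIGH_RATE_GY_PER_YR,
}


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class RadionuclideInventory:
    """Host-rock radionuclide mass fractions in ug/g (ppm by mass)."""

    uranium_ppm: float = 0.0
    thorium_ppm: float = 0.0
    potassium40_ppm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("uranium_ppm", "thorium_ppm", "potassium40_ppm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)!r}")

    def as_dict(self) -> dict[str, float]:
        return {
            "uranium": self.uranium_ppm,
            "thorium": self.thorium_ppm,
            "potassium40": self.potassium40_ppm,
        }


@dataclass(frozen=True)
class ParticleMix:
    """Fractional split of the absorbed dose by particle type.

    Fractions must sum to 1 (within 1e-9).
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in PARTICLES:
            _check_fraction(f"mix.{name}", getattr(self, name))
        total = self.alpha + self.beta + self.gamma
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(
                "mix fractions alpha+beta+gamma must sum to 1 "
                f"(got {total!r} from alpha={self.alpha}, beta={self.beta}, "
                f"gamma={self.gamma})"
            )


@dataclass(frozen=True)
class ParticleWeights:
    """Relative-biological-effectiveness weighting factors per particle type.

    Defaults follow the standard radiation-protection quality factors:
    alpha 20, beta 1, gamma 1.  All weights must be positive; values below
    1 are permitted (weighting is configurable, not prescriptive).
    """

    alpha: float = 20.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in PARTICLES:
            if getattr(self, name) <= 0:
                raise ValidationError(
                    f"weights.{name} must be > 0, got {getattr(self, name)!r}"
                )


DEFAULT_WEIGHTS = ParticleWeights()


@dataclass(frozen=True)
class DoseScenario:
    """A named irradiation regime: absorbed dose rate plus particle mix."""

    name: str
    dose_rate_gy_per_yr: float
    mix: ParticleMix = field(default_factory=ParticleMix)

    def __post_init__(self) -> None:
        if self.dose_rate_gy_per_yr < 0:
            raise ValidationError(
                f"dose_rate_gy_per_yr must be >= 0, got {self.dose_rate_gy_per_yr!r}"
            )


@dataclass(frozen=True)
class RadiolyticYield:
    """Radiolytic yield of one chemical species, in molecules per 100 eV."""

    species: str
    g_value: float

    def __post_init__(self) -> None:
        if self.g_value < 0:
            raise ValidationError(f"g_value must be >= 0, got {self.g_value!r}")


def reference_scenarios() -> list[DoseScenario]:
    """The six study scenarios: two dose rates x three particle mixes.

    Rates are the West Rand low (0.02 Gy/yr) and Vaal Reef high (0.3 Gy/yr)
    presets; mixes are pure gamma, pure alpha, and 50% alpha / 50% gamma.
    """
    mixes = {
        "gamma": ParticleMix(gamma=1.0),
        "alpha": ParticleMix(alpha=1.0, gamma=0.0),
        "alpha_gamma_50_50": ParticleMix(alpha=0.5, gamma=0.5),
    }
    return [
        DoseScenario(name=f"{site}_{mix_name}", dose_rate_gy_per_yr=rate, mix=mix)
        for site, rate in PRESET_RATES.items()
        for mix_name, mix in mixes.items()
    ]


def effective_dose_rate(scenario: DoseScenario, weights: ParticleWeights = DEFAULT_WEIGHTS) -> float:
    """Biologically weighted dose rate in Gy-equivalent per year.

    D_eff = D * (f_alpha * w_alpha + f_beta * w_beta + f_gamma * w_gamma).
    Zero iff the absorbed rate is zero (mix fractions sum to 1 and weights
    are positive).
    """
    m, w = scenario.mix, weights
    return scenario.dose_rate_gy_per_yr * (
        m.alpha * w.alpha + m.beta * w.beta + m.gamma * w.gamma
    )


def accumulated_dose(
    scenario: DoseScenario,
    weights: ParticleWeights = DEFAULT_WEIGHTS,
    years: float = 0.0,
) -> float:
    """Weighted dose (Gy-eq) accumulated over ``years`` at a constant rate."""
    if years < 0:
        raise ValidationError(f"years must be >= 0, got {years!r}")
    return effective_dose_rate(scenario, weights) * years


def dose_rate_from_inventory(
    inventory: RadionuclideInventory,
    coefficients: Mapping[str, Mapping[str, float]],
    name: str = "from_inventory",
) -> DoseScenario:
    """Build a scenario from a linear per-ppm coefficient table.

    ``coefficients`` maps nuclide name ("uranium", "thorium", "potassium40")
    to a per-particle table of Gy/yr per ppm.  The resulting particle mix is
    proportional to the per-particle dose contributions.  Every nuclide with
    a nonzero inventory must have a coefficient entry.
    """
    per_particle = dict.fromkeys(PARTICLES, 0.0)
    for nuclide, ppm in inventory.as_dict().items():
        if ppm == 0:
            continue
        if nuclide not in coefficients:
            raise ConfigurationError(
                f"no dose coefficient for nuclide {nuclide!r} with nonzero "
                f"inventory ({ppm} ppm)"
            )
        for particle, coeff in coefficients[nuclide].items():
            if particle not in PARTICLES:
                raise ConfigurationError(
                    f"unknown particle type {particle!r} in coefficients for {nuclide!r}"
                )
            if coeff < 0:
                raise ConfigurationError(
                    f"coefficient for {nuclide!r}/{particle} must be >= 0, got {coeff!r}"
                )
            per_particle[particle] += ppm * coeff
    total = sum(per_particle.values())
    if total == 0:
        mix = ParticleMix(gamma=1.0)  # arbitrary for a zero-rate scenario
    else:
        mix = ParticleMix(
            alpha=per_particle["alpha"] / total,
            beta=per_particle["beta"] / total,
            gamma=per_particle["gamma"] / total,
        )
    return DoseScenario(name=name, dose_rate_gy_per_yr=total, mix=mix)


def production_rate(
    yld: RadiolyticYield,
    dose_rate_gy_per_yr: float,
    water_density_kg_per_l: float = 1.0,
) -> float:
    """Radiolytic production of a species in mol / L / yr.

    P = (G/100) [molecules/eV] * dose_rate [J/kg/yr] * density [kg/L]
        * eV-per-J / Avogadro.

    Linear in both the G-value and the dose rate.
    """
    if dose_rate_gy_per_yr < 0:
        raise ValidationError(
            f"dose_rate_gy_per_yr must be >= 0, got {dose_rate_gy_per_yr!r}"
        )
    if water_density_kg_per_l < 0:
        raise ValidationError(
            f"water_density_kg_per_l must be >= 0, got {water_density_kg_per_l!r}"
        )
    molecules_per_ev = yld.g_value / 100.0
    ev_per_l_per_yr = dose_rate_gy_per_yr * water_density_kg_per_l * EV_PER_JOULE
    return molecules_per_ev * ev_per_l_per_yr / AVOGADRO


def load_gvalues(path: str | Path | None = None) -> dict[str, RadiolyticYield]:
    """Read a two-column (species, g_value) table; '#' comments allowed.

    With no path, loads the packaged defaults (pure-water gamma radiolysis
    literature values).
    """
    if path is None:
        text = resources.files("radhab.data").joinpath("gvalues.tsv").read_text()
    else:
        text = Path(path).read_text()
    yields: dict[str, RadiolyticYield] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ConfigurationError(
                f"G-value table line {lineno}: expected 'species g_value', got {raw!r}"
            )
        species, g_text = parts
        try:
            g = float(g_text)
        except ValueError:
            raise ConfigurationError(
                f"G-value table line {lineno}: g_value {g_text!r} is not a number"
            ) from None
        yields[species] = RadiolyticYield(species=species, g_value=g)
    return yields


def load_scenario(path: str | Path) -> tuple[DoseScenario, ParticleWeights]:
    """Load a scenario config (YAML or JSON).

    Expected keys: ``name``, ``dose_rate_gy_per_yr``, ``mix`` with
    ``{alpha, beta, gamma}``, and optionally ``weights`` with the same
    particle keys (defaulting to alpha 20 / beta 1 / gamma 1).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: cannot parse scenario config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: scenario config must be a mapping")
    for key in ("name", "dose_rate_gy_per_yr", "mix"):
        if key not in raw:
            raise ConfigurationError(f"{path}: missing required key {key!r}")
    mix_raw = raw["mix"]
    if not isinstance(mix_raw, dict):
        raise ConfigurationError(f"{path}: key 'mix' must be a mapping of particle fractions")
    try:
        mix = ParticleMix(
            alpha=float(mix_raw.get("alpha", 0.0)),
            beta=float(mix_raw.get("beta", 0.0)),
            gamma=float(mix_raw.get("gamma", 0.0)),
        )
        scenario = DoseScenario(
            name=str(raw["name"]),
            dose_rate_gy_per_yr=float(raw["dose_rate_gy_per_yr"]),
            mix=mix,
        )
        weights_raw = raw.get("weights") or {}
        weights = ParticleWeights(
            alpha=float(weights_raw.get("alpha", DEFAULT_WEIGHTS.alpha)),
            beta=float(weights_raw.get("beta", DEFAULT_WEIGHTS.beta)),
            gamma=float(weights_raw.get("gamma", DEFAULT_WEIGHTS.gamma)),
        )
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
    return scenario, weights


def scenario_to_dict(scenario: DoseScenario, weights: ParticleWeights) -> dict:
    """JSON-serialisable view of a scenario + weights (for provenance)."""
    return {
        "name": scenario.name,
        "dose_rate_gy_per_yr": scenario.dose_rate_gy_per_yr,
        "mix": {p: getattr(scenario.mix, p) for p in PARTICLES},
        "weights": {p: getattr(weights, p) for p in PARTICLES},
    }


def dump_scenario(scenario: DoseScenario, weights: ParticleWeights, path: str | Path) -> None:
    """Write a scenario config as JSON (readable back by :func:`load_scenario`)."""
    Path(path).write_text(json.dumps(scenario_to_dict(scenario, weights), indent=2) + "\n")
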