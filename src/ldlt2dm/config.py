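"""Run and simulation configuration.

Two dataclasses hold every tunable number in the pipeline:

* :class:`SimulationConfig` — parameters of the synthetic EHR generator
  (population size, true exposure effect, covariate effects, contamination
  rates that exercise the cohort filters).
* :class:`RunConfig` — paths, seeds, cohort thresholds and analysis toggles
  for an end-to-end run.

Both validate eagerly and raise :class:`ConfigError` naming the offending
field, so a bad YAML file fails before any table is generated.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "RunConfig",
    "DEFAULT_COVARIATE_EFFECTS",
    "load_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Invalid configuration value; the message names the field."""


#: Log-odds of T2DM per unit of each covariate (age in years, BMI in kg/m²;
#: male and african_ancestry are indicators). Magnitudes are conventional
#: epidemiological effect sizes for type 2 diabetes risk.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age": 0.045,
    "male": 0.25,
    "african_ancestry": 0.40,
    "bmi": 0.09,
}


def _check_prob(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and 0.0 <= value <= 1.0):
        raise ConfigError(f"{name}: expected a proportion in [0, 1], got {value!r}")


def _check_finite(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ConfigError(f"{name}: expected a finite number, got {value!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic EHR generator.

    The defaults describe the study conditions the generator emulates: a
    lipid-screened hospital population in which roughly one patient in nine
    has very low LDL-C, the latent type 2 diabetes liability depends on LDL
    group, age, sex, ancestry and BMI, and a configurable fraction of
    records carry the artefacts (statin mentions, inpatient labs,
    hypoalbuminemia, paediatric measurements) that the cohort filters must
    remove.
    """

    n_patients: int = 20_000
    seed: int = 0
    #: natural-log odds ratio of T2DM for the low vs normal LDL-C group
    true_log_or_low_ldl: float = math.log(2.0)
    #: T2DM log-odds at the covariate reference point (age 45, female,
    #: European ancestry, BMI 27)
    baseline_t2dm_logit: float = -2.9
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    frac_low_ldl: float = 0.111
    #: extra lipid panels per patient beyond the guaranteed first (Poisson mean)
    mean_extra_panels: float = 2.0
    # --- contamination rates; each exercises one cohort filter -------------
    frac_statin: float = 0.10
    frac_inpatient_panel: float = 0.05
    frac_low_albumin: float = 0.03
    frac_under5_panel: float = 0.02
    # --- rarer record features used by sensitivity filters -----------------
    frac_ezetimibe: float = 0.02
    frac_cvd_codes: float = 0.04
    frac_renal_codes: float = 0.01
    frac_transplant_codes: float = 0.005
    frac_stroke_codes: float = 0.01
    frac_low_egfr: float = 0.01
    frac_direct_ldl: float = 0.05
    # --- record-window geometry --------------------------------------------
    window_start: str = "2000-01-01"
    window_years: float = 20.0

    def __post_init__(self) -> None:
        if not isinstance(self.n_patients, int) or self.n_patients < 0:
            raise ConfigError(f"n_patients: expected a non-negative integer, got {self.n_patients!r}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed: expected a non-negative integer, got {self.seed!r}")
        _check_finite("true_log_or_low_ldl", self.true_log_or_low_ldl)
        _check_finite("baseline_t2dm_logit", self.baseline_t2dm_logit)
        for key in ("age", "male", "african_ancestry", "bmi"):
            if key not in self.covariate_effects:
                raise ConfigError(f"covariate_effects: missing required key {key!r}")
            _check_finite(f"covariate_effects[{key}]", self.covariate_effects[key])
        for name in (
            "frac_low_ldl",
            "frac_statin",
            "frac_inpatient_panel",
            "frac_low_albumin",
            "frac_under5_panel",
            "frac_ezetimibe",
            "frac_cvd_codes",
            "frac_renal_codes",
            "frac_transplant_codes",
            "frac_stroke_codes",
            "frac_low_egfr",
            "frac_direct_ldl",
        ):
            _check_prob(name, getattr(self, name))
        if not (math.isfinite(self.mean_extra_panels) and self.mean_extra_panels >= 0):
            raise ConfigError(f"mean_extra_panels: expected a non-negative number, got {self.mean_extra_panels!r}")
        if not (math.isfinite(self.window_years) and self.window_years > 0):
            raise ConfigError(f"window_years: expected a positive number, got {self.window_years!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def zero_contamination(self) -> "SimulationConfig":
        """Copy with every contamination pathway switched off."""
        return replace(
            self,
            frac_statin=0.0,
            frac_inpatient_panel=0.0,
            frac_low_albumin=0.0,
            frac_under5_panel=0.0,
        )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["covariate_effects"] = dict(self.covariate_effects)
        return d


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Cohort thresholds default to the study definition: low group median
    LDL-C ≤ 60 mg/dl with no measurement ever ≥ 80; normal group median in
    [90, 130] with no measurement ever ≥ 150 or ≤ 80; hypoalbuminemia below
    3 g/dl invalidates LDL-C measurements within ±30 days.
    """

    seed: int = 0
    out_dir: str = "out"
    # input tables; None → simulate with `simulation`
    patients_csv: str | None = None
    labs_csv: str | None = None
    codes_csv: str | None = None
    meds_csv: str | None = None
    phecode_map_csv: str | None = None  # None → bundled miniature map
    phecode_exclusions_csv: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # cohort thresholds (mg/dl)
    low_median_max: float = 60.0
    low_reading_max: float = 80.0
    normal_median_min: float = 90.0
    normal_median_max: float = 130.0
    normal_reading_max: float = 150.0
    albumin_threshold: float = 3.0  # g/dl
    albumin_window_days: int = 30
    discovery_fraction: float = 1.0 / 3.0
    alpha: float = 0.05
    # toggles
    tg_over_400_filter: bool = True
    continuity_correction: bool = False
    substitute_4339x_for_3349: bool = False
    force_validation: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed: expected a non-negative integer, got {self.seed!r}")
        thresholds = (
            self.low_median_max,
            self.low_reading_max,
            self.normal_median_min,
            self.normal_median_max,
            self.normal_reading_max,
        )
        for name, value in zip(
            ("low_median_max", "low_reading_max", "normal_median_min", "normal_median_max", "normal_reading_max"),
            thresholds,
        ):
            _check_finite(name, value)
        if not (thresholds[0] <= thresholds[1] <= thresholds[2] <= thresholds[3] <= thresholds[4]):
            raise ConfigError(
                "group thresholds: require low_median_max <= low_reading_max <= "
                "normal_median_min <= normal_median_max <= normal_reading_max, "
                f"got {thresholds}"
            )
        if not (0.0 < self.discovery_fraction < 1.0):
            raise ConfigError(f"discovery_fraction: expected a fraction in (0, 1), got {self.discovery_fraction!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha: expected a level in (0, 1), got {self.alpha!r}")
        if self.albumin_window_days < 0:
            raise ConfigError(f"albumin_window_days: expected >= 0, got {self.albumin_window_days!r}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) file; ``seed`` overrides the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path}: expected a mapping at top level")
    sim_raw = raw.pop("simulation", {})
    try:
        sim = SimulationConfig(**sim_raw)
        cfg = RunConfig(simulation=sim, **raw)
    except TypeError as exc:  # unknown field
        raise ConfigError(str(exc)) from exc
    if seed is not None:
        cfg = replace(cfg, seed=seed, simulation=replace(cfg.simulation, seed=seed))
    return cfg


def config_hash(cfg: RunConfig | SimulationConfig) -> str:
    """Stable short hash of a config, recorded in every output artifact.

    Storage locations (``out_dir`` and input paths) are excluded: the hash
    fingerprints the scientific configuration, so the same analysis written
    to two directories carries the same hash.
    """
    d = cfg.to_dict()
    for key in ("out_dir", "patients_csv", "labs_csv", "codes_csv", "meds_csv",
                "phecode_map_csv", "phecode_exclusions_csv"):
        d.pop(key, None)
    payload = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
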