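"""Model parameterization: types, validation, serialization, defaults.

The configuration is split into four blocks mirroring the structure of the
model: the natural course of illness (incidence, remission, recurrence),
the healthcare services (prevention, treatment, aftercare), demography
(life table, excess mortality) and simulation settings (replicates, seeds,
confidence level).

All stored quantities are per-period *probabilities*, never rates; period
changes always go through the complement-power formula
``1 - (1 - p) ** (target / source)`` (see :func:`convert_probability`).
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

__all__ = [
    "CourseParams",
    "ServiceParams",
    "DemographyParams",
    "SimulationSettings",
    "ModelConfig",
    "convert_probability",
    "default_config",
    "null_config",
    "validate_config",
    "load_config",
    "save_config",
    "set_param",
    "FEMALE",
    "MALE",
]

#: integer sex codes used throughout the package (column order of life-table
#: and hazard arrays)
FEMALE, MALE = 0, 1
SEX_NAMES = ("female", "male")


# ---------------------------------------------------------------------------
# probability/period conversion
# ---------------------------------------------------------------------------

def convert_probability(p: float, source_period_months: float,
                        target_period_months: float) -> float:
    """Convert a cumulative transition probability between period lengths.

    Assumes a constant hazard within the source period, so the probability
    over ``target`` months is ``1 - (1 - p) ** (target / source)``.  The
    canonical use is the 12-month -> 1-month conversion: a 53% yearly
    spontaneous remission probability becomes a 6.098% monthly probability.

    Parameters
    ----------
    p : float
        Cumulative probability over ``source_period_months``, in [0, 1].
    source_period_months, target_period_months : float
        Positive period lengths (months).

    Returns
    -------
    float
        Cumulative probability over the target period.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p!r}")
    if source_period_months <= 0 or target_period_months <= 0:
        raise ValueError("period lengths must be positive")
    if p == 1.0:
        return 1.0
    return float(-np.expm1(np.log1p(-p) * (target_period_months / source_period_months)))


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class IncidenceProfile:
    """Piecewise-constant age profile of the yearly first-onset probability.

    ``multipliers[i]`` applies from ``age_bands[i]`` (years) up to the next
    band start.  The same shape is used for both sexes unless the per-sex
    scales are overridden.  The absolute level is
    ``yearly_incidence_overall * incidence_scale * multiplier * sex_scale``;
    the scale is a calibration output chosen so that simulated lifetime
    incidence matches the epidemiological target (11.4%).
    """

    age_bands: list[int] = field(default_factory=lambda: [0, 15, 25, 35, 45, 55, 65, 75])
    multipliers: list[float] = field(default_factory=lambda: [0.2, 1.6, 1.4, 1.1, 0.9, 0.7, 0.5, 0.3])
    female_scale: float = 1.0
    male_scale: float = 1.0

    def yearly_by_age_month(self, yearly_overall: float, scale: float,
                            max_age_months: int) -> np.ndarray:
        """Effective yearly onset probability per (age month, sex)."""
        ages_y = np.arange(max_age_months) // 12
        idx = np.searchsorted(np.asarray(self.age_bands), ages_y, side="right") - 1
        mult = np.asarray(self.multipliers, dtype=float)[idx]
        base = yearly_overall * scale * mult
        out = np.stack([base * self.female_scale, base * self.male_scale], axis=1)
        return np.clip(out, 0.0, 1.0)


@dataclass
class RemissionDecay:
    """Decline of the recurrence hazard with time spent in remission.

    ``exponential`` multiplies the month-1 hazard by ``exp(-rate * (t - 1))``
    after ``t`` months in remission, so the printed month-1 values (2.36% /
    2.74%) are exact regardless of the rate.  The default rate is a
    calibration output targeting the 54% lifetime recurrence fraction.
    """

    form: str = "exponential"
    rate: float = 0.03

    def factor(self, months_in_remission):
        t = np.asarray(months_in_remission, dtype=float)
        if self.form == "exponential":
            return np.exp(-self.rate * (t - 1.0))
        if self.form == "none":
            return np.ones_like(t)
        raise ValueError(f"unknown remission decay form {self.form!r}")


@dataclass
class CourseParams:
    """Natural-course parameters of depression."""

    yearly_incidence_overall: float = 0.0114
    incidence_scale: float = 1.0
    incidence_profile: IncidenceProfile = field(default_factory=IncidenceProfile)
    remission_milestones: tuple[float, float, float] = (0.23, 0.32, 0.53)
    remission_monthly_base: float = 0.06098
    remission_mode: str = "flat"  # "flat" | "piecewise"
    recurrence_monthly_base: float = 0.0236
    episode_risk_multiplier: float = 1.16
    remission_decay: RemissionDecay = field(default_factory=RemissionDecay)
    max_hazard_cap: float = 1.0

    def spontaneous_remission_by_duration(self, max_months: int) -> np.ndarray:
        """Monthly spontaneous remission probability, indexed by months in
        the current episode (index 0 unused; episodes are >= 1 month in).

        ``flat`` uses the 12-month milestone converted to one month for every
        episode month; ``piecewise`` matches all three milestones (cumulative
        23%/32%/53% at months 3/6/12) and stays constant afterwards.
        """
        h = np.full(max_months + 2, self.remission_monthly_base, dtype=float)
        if self.remission_mode == "piecewise":
            m3, m6, m12 = self.remission_milestones
            h[1:4] = convert_probability(m3, 3, 1)
            h[4:7] = convert_probability(1 - (1 - m6) / (1 - m3), 3, 1)
            h[7:13] = convert_probability(1 - (1 - m12) / (1 - m6), 6, 1)
            h[13:] = self.remission_monthly_base
        elif self.remission_mode != "flat":
            raise ValueError(f"unknown remission mode {self.remission_mode!r}")
        return h


@dataclass
class ServiceParams:
    """Reach and effectiveness of prevention, treatment and aftercare.

    ``*_reach`` are population fractions; ``treatment_reach`` is the
    12-month cumulative probability that a diseased individual seeks help.
    ``prevention_effect`` and ``aftercare_effect`` multiply the relevant
    monthly hazard by ``1 - effect``; ``treatment_effect`` multiplies the
    monthly remission probability by ``1 + effect``.
    """

    prevention_reach: float = 0.05
    prevention_effect: float = 0.21
    prevention_applies_to_recurrence: bool = False
    treatment_reach: float = 0.33
    treatment_effect: float = 0.62
    aftercare_reach: float = 0.50
    aftercare_effect: float = 0.36
    waiting_mean: float = 5.0
    waiting_sd: float = 1.0
    treatment_max_duration: int = 24
    aftercare_max_duration: int = 12
    retreatment_lockout: bool = False
    #: what happens when an ever-treated individual relapses: "memoryless"
    #: restarts the monthly seek-and-wait process from scratch; "no_wait"
    #: keeps the monthly help-seeking decision but skips the waiting queue
    #: (the therapist is known, care is established); "immediate" re-enters
    #: treatment in the first month of the new episode without seeking
    retreatment: str = "no_wait"

    @property
    def monthly_seek_probability(self) -> float:
        """Per diseased month help-seeking probability such that the
        12-month cumulative probability equals ``treatment_reach``."""
        return convert_probability(self.treatment_reach, 12, 1)


@dataclass
class DemographyParams:
    """Life table, cohort composition and depression excess mortality."""

    life_table: str = "default"  # "default" or a CSV path
    sex_ratio_at_entry: float = 0.5  # fraction female
    excess_mortality_rr: dict = field(default_factory=lambda: {"female": 1.6, "male": 1.8})
    max_age_months: int = 1320

    _q_month: np.ndarray | None = field(default=None, repr=False, compare=False)

    def monthly_mortality(self) -> np.ndarray:
        """Baseline monthly death probability, shape ``(max_age_months, 2)``
        with columns (female, male); equals 1 in the final month."""
        if self._q_month is None:
            self._q_month = _load_life_table(self.life_table, self.max_age_months)
        return self._q_month

    def rr_vector(self) -> np.ndarray:
        return np.array([self.excess_mortality_rr["female"],
                         self.excess_mortality_rr["male"]], dtype=float)


@dataclass
class SimulationSettings:
    n_runs: int = 1000
    n_lives_per_run: int = 10000
    base_seed: int = 20240402
    ci_level: float = 0.95
    common_random_numbers: bool = True


@dataclass
class ModelConfig:
    course: CourseParams = field(default_factory=CourseParams)
    services: ServiceParams = field(default_factory=ServiceParams)
    demography: DemographyParams = field(default_factory=DemographyParams)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "ModelConfig":
        new = copy.deepcopy(self)
        return new


# ---------------------------------------------------------------------------
# life table loading
# ---------------------------------------------------------------------------

def _load_life_table(source: str, max_age_months: int) -> np.ndarray:
    """Load a life table CSV and expand it to a monthly (age, sex) array.

    Accepts either yearly rows (age_years, sex, q_year) or monthly rows
    (age_months, sex, q_month).  Yearly probabilities are expanded with
    constant hazard within the year.  The final month is forced to 1
    (closed cohort).
    """
    if source == "default":
        ref = importlib.resources.files("depsim.data") / "life_table_default.csv"
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    import pandas as pd

    df = pd.read_csv(io.StringIO(text))
    q = np.zeros((max_age_months, 2), dtype=float)
    if "age_years" in df.columns:
        for s, name in enumerate(SEX_NAMES):
            sub = df[df["sex"] == name].sort_values("age_years")
            q_year = sub["q_year"].to_numpy()
            ages = sub["age_years"].to_numpy()
            month_ages = np.arange(max_age_months) // 12
            idx = np.clip(np.searchsorted(ages, month_ages, side="right") - 1, 0, len(ages) - 1)
            q[:, s] = 1.0 - (1.0 - q_year[idx]) ** (1.0 / 12.0)
    elif "age_months" in df.columns:
        for s, name in enumerate(SEX_NAMES):
            sub = df[df["sex"] == name].sort_values("age_months")
            n = min(max_age_months, len(sub))
            q[:n, s] = sub["q_month"].to_numpy()[:n]
    else:
        raise ValueError("life table must have age_years/q_year or age_months/q_month columns")
    q[-1, :] = 1.0
    return np.clip(q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# defaults / null scenario
# ---------------------------------------------------------------------------

def default_config() -> ModelConfig:
    """The status-quo parameterization of the current healthcare system.

    Values printed in the literature are set directly; the incidence-profile
    scale and the remission-decay rate are calibration outputs bundled in
    ``data/defaults_paper.cfg`` (targets: 11.4% lifetime incidence, 54%
    recurrence fraction).
    """
    ref = importlib.resources.files("depsim.data") / "defaults_paper.cfg"
    return load_config(io.StringIO(ref.read_text()))


def null_config(cfg: ModelConfig) -> ModelConfig:
    """Copy of ``cfg`` with no healthcare: all three service reaches 0."""
    out = cfg.copy()
    out.services.prevention_reach = 0.0
    out.services.treatment_reach = 0.0
    out.services.aftercare_reach = 0.0
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check(violations, ok, name, rule):
    if not ok:
        violations.append(f"{name}: {rule}")


def validate_config(cfg: ModelConfig) -> list[str]:
    """Return a list of invariant violations (empty iff the config is valid).

    Violations are data, not exceptions: each entry names the offending
    field and the rule it breaks.
    """
    v: list[str] = []
    c, s, d, sim = cfg.course, cfg.services, cfg.demography, cfg.simulation

    def prob(x, name):
        _check(v, 0.0 <= x <= 1.0, name, f"must be in [0, 1], got {x}")

    prob(c.yearly_incidence_overall, "course.yearly_incidence_overall")
    _check(v, c.incidence_scale >= 0, "course.incidence_scale", "must be >= 0")
    _check(v, len(c.incidence_profile.age_bands) == len(c.incidence_profile.multipliers),
           "course.incidence_profile", "age_bands and multipliers must have equal length")
    _check(v, all(m >= 0 for m in c.incidence_profile.multipliers),
           "course.incidence_profile.multipliers", "must be nonnegative")
    _check(v, list(c.incidence_profile.age_bands) == sorted(set(c.incidence_profile.age_bands)),
           "course.incidence_profile.age_bands", "must be strictly increasing")
    ms = c.remission_milestones
    for m in ms:
        prob(m, "course.remission_milestones")
    _check(v, ms[0] < ms[1] < ms[2], "course.remission_milestones", "not increasing")
    prob(c.remission_monthly_base, "course.remission_monthly_base")
    prob(c.recurrence_monthly_base, "course.recurrence_monthly_base")
    _check(v, c.episode_risk_multiplier >= 1, "course.episode_risk_multiplier", "must be >= 1")
    _check(v, c.remission_decay.rate >= 0, "course.remission_decay.rate", "must be >= 0")
    _check(v, c.remission_mode in ("flat", "piecewise"), "course.remission_mode",
           "must be 'flat' or 'piecewise'")
    _check(v, c.max_hazard_cap == 1.0 or 0 < c.max_hazard_cap <= 1.0,
           "course.max_hazard_cap", "must be in (0, 1]")

    for name in ("prevention_reach", "prevention_effect", "treatment_reach",
                 "aftercare_reach", "aftercare_effect"):
        prob(getattr(s, name), f"services.{name}")
    _check(v, s.treatment_effect >= 0, "services.treatment_effect", "must be >= 0")
    _check(v, s.waiting_sd >= 0, "services.waiting_sd", "must be >= 0")
    _check(v, s.waiting_mean >= 0, "services.waiting_mean", "must be >= 0")
    _check(v, isinstance(s.treatment_max_duration, int) and s.treatment_max_duration > 0,
           "services.treatment_max_duration", "must be a positive integer")
    _check(v, isinstance(s.aftercare_max_duration, int) and s.aftercare_max_duration > 0,
           "services.aftercare_max_duration", "must be a positive integer")
    _check(v, s.retreatment in ("immediate", "no_wait", "memoryless"),
           "services.retreatment", "must be 'immediate', 'no_wait' or 'memoryless'")

    prob(d.sex_ratio_at_entry, "demography.sex_ratio_at_entry")
    for k in ("female", "male"):
        _check(v, d.excess_mortality_rr.get(k, 0) >= 1,
               f"demography.excess_mortality_rr.{k}", "must be >= 1")
    _check(v, d.max_age_months > 0, "demography.max_age_months", "must be positive")
    try:
        q = d.monthly_mortality()
        _check(v, np.all((q >= 0) & (q <= 1)), "demography.life_table",
               "mortality probabilities must be in [0, 1]")
        _check(v, np.all(q[-1] == 1.0), "demography.life_table",
               "final-month mortality must equal 1")
    except (OSError, ValueError) as e:  # unreadable table is itself a violation
        v.append(f"demography.life_table: {e}")

    _check(v, sim.n_runs >= 1, "simulation.n_runs", "must be >= 1")
    _check(v, sim.n_lives_per_run >= 1, "simulation.n_lives_per_run", "must be >= 1")
    _check(v, 0.0 < sim.ci_level < 1.0, "simulation.ci_level", "must be in (0, 1)")
    return v


# ---------------------------------------------------------------------------
# serialization (YAML, strict keys)
# ---------------------------------------------------------------------------

_BLOCKS = {"course": CourseParams, "services": ServiceParams,
           "demography": DemographyParams, "simulation": SimulationSettings}


def _to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        if f.name.startswith("_"):
            continue
        val = getattr(obj, f.name)
        if dataclasses.is_dataclass(val):
            out[f.name] = _to_dict(val)
        elif isinstance(val, tuple):
            out[f.name] = list(val)
        else:
            out[f.name] = val
    return out


def _from_dict(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls) if not f.name.startswith("_")}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, val in data.items():
        ftype = fields[name].type
        if name == "incidence_profile":
            kwargs[name] = _from_dict(IncidenceProfile, val)
        elif name == "remission_decay":
            kwargs[name] = _from_dict(RemissionDecay, val)
        elif name == "remission_milestones":
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    return cls(**kwargs)


def config_to_dict(cfg: ModelConfig) -> dict:
    d = {name: _to_dict(getattr(cfg, name)) for name in _BLOCKS}
    if cfg.metadata:
        d["metadata"] = cfg.metadata
    return d


def config_from_dict(data: dict) -> ModelConfig:
    unknown = set(data) - set(_BLOCKS) - {"metadata"}
    if unknown:
        raise ValueError(f"unknown top-level config sections: {sorted(unknown)}")
    kwargs = {name: _from_dict(cls, data.get(name, {})) for name, cls in _BLOCKS.items()}
    return ModelConfig(metadata=data.get("metadata", {}), **kwargs)


def load_config(path_or_file) -> ModelConfig:
    """Load a config from a YAML file path or file-like object.

    Unknown keys at any level are an error (fail loudly rather than silently
    ignoring a misspelled parameter).
    """
    if hasattr(path_or_file, "read"):
        data = yaml.safe_load(path_or_file.read())
    else:
        data = yaml.safe_load(Path(path_or_file).read_text())
    return config_from_dict(data or {})


def save_config(cfg: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


# ---------------------------------------------------------------------------
# parameter paths (used by sweeps and calibration)
# ---------------------------------------------------------------------------

def get_param(cfg: ModelConfig, path: str) -> Any:
    obj: Any = cfg
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def set_param(cfg: ModelConfig, path: str, value: Any) -> ModelConfig:
    """Return a copy of ``cfg`` with the dotted-path parameter replaced."""
    out = cfg.copy()
    parts = path.split(".")
    obj: Any = out
    for part in parts[:-1]:
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise ValueError(f"unknown parameter path {path!r}")
    setattr(obj, parts[-1], value)
    return out
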