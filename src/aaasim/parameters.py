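"""Hierarchical parameter bundles.

The simulator's parameters form a strict hierarchy: *global fixed* parameters
(costs known with certainty, waiting times, discount rates, the life table,
measurement-error SDs, the baseline diameter distribution, ...) are scalars or
small structures; *global uncertain* parameters (attendance, operative
mortality probabilities, the EVAR proportion, ...) are distribution
specifications whose realizations are drawn once per probabilistic
sensitivity analysis iteration.  Below these sit pair-specific latent values
(shared by a twin pair), individual-specific values (intervention arm) and
event-specific values (a fresh measurement error per scan); those lower
levels are generated in the engine, never stored here.

A bundle is a single human-readable YAML file.  All durations are exposed in
years internally; the two surgical waiting times are stored in days in the
file and converted at 365.25 d/y.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "LifeTable",
    "ParameterBundle",
    "GlobalUncertainDraw",
    "load_bundle",
    "save_bundle",
    "draw_global_uncertain",
    "fix_bundle_at_means",
    "builtin_bundle_names",
]

DAYS_PER_YEAR = 365.25

_FAMILIES = ("fixed", "beta", "normal", "lognormal", "gamma")


class BundleValidationError(ValueError):
    """A parameter bundle failed validation."""


@dataclass(frozen=True)
class DistributionSpec:
    """Specification of one global uncertain parameter.

    ``family`` is one of ``fixed`` (point mass, parameter ``value``),
    ``beta`` (``alpha``, ``beta``), ``normal`` (``mu``, ``sigma``),
    ``lognormal`` (``mu``, ``sigma`` on the log scale) or ``gamma``
    (``shape``, ``scale``).  ``probability=True`` requires support within
    [0, 1] (beta, or a fixed value in [0, 1]).
    """

    family: str
    params: Mapping[str, float]
    probability: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))

    def validate(self, name: str) -> None:
        p = self.params
        if self.family not in _FAMILIES:
            raise BundleValidationError(
                f"{name}: unknown distribution family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        try:
            if self.family == "fixed":
                float(p["value"])
            elif self.family == "beta":
                if p["alpha"] <= 0 or p["beta"] <= 0:
                    raise BundleValidationError(
                        f"{name}: beta shapes must be positive, got "
                        f"alpha={p['alpha']}, beta={p['beta']}"
                    )
            elif self.family == "normal":
                if p["sigma"] < 0:
                    raise BundleValidationError(f"{name}: normal sigma must be >= 0")
            elif self.family == "lognormal":
                if p["sigma"] < 0:
                    raise BundleValidationError(f"{name}: lognormal sigma must be >= 0")
            elif self.family == "gamma":
                if p["shape"] <= 0 or p["scale"] <= 0:
                    raise BundleValidationError(
                        f"{name}: gamma shape and scale must be positive"
                    )
        except KeyError as exc:
            raise BundleValidationError(
                f"{name}: missing parameter {exc.args[0]!r} for family {self.family!r}"
            ) from None
        if self.probability:
            if self.family == "fixed":
                v = float(p["value"])
                if not 0.0 <= v <= 1.0:
                    raise BundleValidationError(
                        f"{name}: probability-valued fixed spec must lie in [0, 1], got {v}"
                    )
            elif self.family != "beta":
                raise BundleValidationError(
                    f"{name}: probability-valued parameters must use a beta or fixed "
                    f"spec (support within [0, 1]); got family {self.family!r}"
                )

    def mean(self) -> float:
        p = self.params
        if self.family == "fixed":
            return float(p["value"])
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "normal":
            return float(p["mu"])
        if self.family == "lognormal":
            return math.exp(p["mu"] + p["sigma"] ** 2 / 2.0)
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        raise AssertionError(self.family)

    def variance(self) -> float:
        p = self.params
        if self.family == "fixed":
            return 0.0
        if self.family == "beta":
            a, b = p["alpha"], p["beta"]
            return a * b / ((a + b) ** 2 * (a + b + 1.0))
        if self.family == "normal":
            return float(p["sigma"]) ** 2
        if self.family == "lognormal":
            s2 = p["sigma"] ** 2
            return (math.exp(s2) - 1.0) * math.exp(2.0 * p["mu"] + s2)
        if self.family == "gamma":
            return p["shape"] * p["scale"] ** 2
        raise AssertionError(self.family)

    def draw(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "fixed":
            return float(p["value"])
        if self.family == "beta":
            return float(rng.beta(p["alpha"], p["beta"]))
        if self.family == "normal":
            return float(rng.normal(p["mu"], p["sigma"]))
        if self.family == "lognormal":
            return float(math.exp(rng.normal(p["mu"], p["sigma"])))
        if self.family == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        raise AssertionError(self.family)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"family": self.family, **self.params}
        if self.probability:
            d["probability"] = True
        return d

    @classmethod
    def from_dict(cls, name: str, d: Mapping[str, Any]) -> "DistributionSpec":
        d = dict(d)
        family = d.pop("family", None)
        if family is None:
            raise BundleValidationError(f"{name}: distribution spec missing 'family'")
        probability = bool(d.pop("probability", False))
        spec = cls(family=family, params=d, probability=probability)
        spec.validate(name)
        return spec


class LifeTable:
    """Non-AAA mortality as a piecewise-constant hazard by integer age.

    Built either from an explicit list of annual hazards or from a Gompertz
    law h(age) = a * exp(b * age), tabulated per year of age between
    ``start_age`` and ``max_age`` (everyone alive at ``max_age`` dies there).
    """

    def __init__(self, start_age: int, annual_hazards: np.ndarray, source: dict):
        hz = np.asarray(annual_hazards, dtype=float)
        if hz.ndim != 1 or hz.size == 0:
            raise BundleValidationError("life_table: need a 1-d non-empty hazard list")
        if np.any(hz < 0):
            raise BundleValidationError("life_table: hazards must be >= 0")
        self.start_age = int(start_age)
        self.annual_hazards = hz
        self.max_age = self.start_age + hz.size
        self._cum = np.concatenate([[0.0], np.cumsum(hz)])
        self._source = source

    def sample_death_time(self, entry_age: float, rng: np.random.Generator) -> float:
        """Years from entry (at ``entry_age``) to non-AAA death, by inverse transform."""
        offset = entry_age - self.start_age
        if offset < 0:
            raise ValueError("entry age before start of life table")
        i0 = int(offset)
        # cumulative hazard accrued between start_age and entry is irrelevant:
        # sample conditional on survival to entry.
        e = rng.exponential()
        # cumulative hazard measured from entry
        frac = offset - i0
        cum_entry = self._cum[i0] + frac * self.annual_hazards[i0] if i0 < self.annual_hazards.size else self._cum[-1]
        target = cum_entry + e
        if target >= self._cum[-1]:
            return self.max_age - entry_age
        j = int(np.searchsorted(self._cum, target, side="right")) - 1
        h = self.annual_hazards[j]
        t_abs = j + (target - self._cum[j]) / h  # years since start_age
        return t_abs - offset

    def to_dict(self) -> dict:
        return copy.deepcopy(self._source)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LifeTable":
        d = dict(d)
        kind = d.get("kind")
        if kind == "gompertz":
            start = int(d["start_age"])
            stop = int(d["max_age"])
            ages = np.arange(start, stop)
            hz = float(d["a"]) * np.exp(float(d["b"]) * ages)
            return cls(start, hz, dict(d))
        if kind == "rates":
            return cls(int(d["start_age"]), np.asarray(d["annual_hazards"], float), dict(d))
        raise BundleValidationError(
            f"life_table: unknown kind {kind!r}; expected 'gompertz' or 'rates'"
        )


_REQUIRED_FIXED = (
    "invitation_age",
    "time_horizon_years",
    "censoring",
    "discount_rate_costs",
    "discount_rate_effects",
    "wait_discovery_to_consultation_days",
    "wait_consultation_to_surgery_days",
    "ct_offset_cm",
    "ultrasound_sd_cm",
    "ct_sd_cm",
    "baseline_diameter",
    "zero_growth_cutoff_cm",
    "growth_bands",
    "rupture_hazard",
    "life_table",
    "utilities",
    "costs",
    "oversampling",
    "policy",
)

_COST_ITEMS = (
    "invitation",
    "ultrasound_scan",
    "consultation",
    "elective_open",
    "elective_evar",
    "emergency_open",
    "emergency_evar",
)

# behavioural parameters the engine needs; each may live in global_fixed (a
# scalar) or in global_uncertain (a distribution spec), but must exist somewhere
_BEHAVIOURAL = (
    "attendance",
    "p_dropout_per_visit",
    "p_contraindicated",
    "p_death_emergency",
    "p_death_elective_open",
    "p_death_elective_evar",
    "evar_proportion",
    "prob_emergency_surgery_given_rupture",
    "incidental_detection_rate_per_year",
)

_TOP_KEYS = ("name", "notes", "global_fixed", "global_uncertain")


@dataclass
class ParameterBundle:
    """Validated hierarchical parameter set for one simulator configuration."""

    name: str
    global_fixed: dict
    global_uncertain_specs: dict[str, DistributionSpec]
    notes: dict = field(default_factory=dict)

    # -- derived conveniences ------------------------------------------------
    @property
    def invitation_age(self) -> float:
        return float(self.global_fixed["invitation_age"])

    @property
    def time_horizon_years(self) -> float:
        return float(self.global_fixed["time_horizon_years"])

    @property
    def wait_discovery_to_consultation_years(self) -> float:
        return float(self.global_fixed["wait_discovery_to_consultation_days"]) / DAYS_PER_YEAR

    @property
    def wait_consultation_to_surgery_years(self) -> float:
        return float(self.global_fixed["wait_consultation_to_surgery_days"]) / DAYS_PER_YEAR

    @property
    def life_table(self) -> LifeTable:
        return self._life_table

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        gf = self.global_fixed
        missing = [k for k in _REQUIRED_FIXED if k not in gf]
        if missing:
            raise BundleValidationError(
                f"bundle {self.name!r}: missing global_fixed parameters: {missing}"
            )
        unknown = [
            k
            for k in gf
            if k not in _REQUIRED_FIXED and k not in _BEHAVIOURAL
        ]
        if unknown:
            raise BundleValidationError(
                f"bundle {self.name!r}: unknown global_fixed parameters: {unknown}"
            )
        for rate_key in ("discount_rate_costs", "discount_rate_effects"):
            if gf[rate_key] < 0:
                raise BundleValidationError(f"{rate_key} must be >= 0")
        for wait_key in (
            "wait_discovery_to_consultation_days",
            "wait_consultation_to_surgery_days",
        ):
            if gf[wait_key] < 0:
                raise BundleValidationError(f"{wait_key} must be >= 0")
        if gf["time_horizon_years"] <= 0:
            raise BundleValidationError("time_horizon_years must be > 0")
        if gf["ultrasound_sd_cm"] < 0 or gf["ct_sd_cm"] < 0:
            raise BundleValidationError("measurement SDs must be >= 0")
        cens = gf["censoring"]
        if cens.get("kind") not in ("horizon", "uniform"):
            raise BundleValidationError(
                "censoring.kind must be 'horizon' or 'uniform'"
            )
        if cens["kind"] == "uniform" and not (0 <= cens["low"] < cens["high"]):
            raise BundleValidationError("uniform censoring needs 0 <= low < high")
        bd = gf["baseline_diameter"]
        if bd.get("family") != "lognormal" or bd.get("sigma", -1) < 0:
            raise BundleValidationError(
                "baseline_diameter must be a lognormal spec with sigma >= 0"
            )
        bands = gf["growth_bands"]
        lowers = [b["lower_cm"] for b in bands]
        if lowers != sorted(lowers) or len(set(lowers)) != len(lowers):
            raise BundleValidationError("growth_bands lower_cm must be strictly increasing")
        for b in bands:
            if b["sd"] < 0:
                raise BundleValidationError("growth band sd must be >= 0")
        hz = gf["rupture_hazard"]
        for k in ("intercept", "slope", "reference_diameter_cm"):
            if k not in hz:
                raise BundleValidationError(f"rupture_hazard missing {k!r}")
        missing_cost = [c for c in _COST_ITEMS if c not in gf["costs"]]
        if missing_cost:
            raise BundleValidationError(f"costs missing items: {missing_cost}")
        for item, v in gf["costs"].items():
            if item not in _COST_ITEMS:
                raise BundleValidationError(f"unknown cost item {item!r}")
            if v < 0:
                raise BundleValidationError(f"cost {item!r} must be >= 0")
        os_ = gf["oversampling"]
        if not (0 < os_.get("target_stratum_fraction", 0.5) < 1):
            raise BundleValidationError("oversampling target_stratum_fraction in (0,1)")
        for name, spec in self.global_uncertain_specs.items():
            spec.validate(name)
        # probability-valued behavioural parameters must have [0,1] support
        for pname in _BEHAVIOURAL:
            in_fixed = pname in gf
            in_unc = pname in self.global_uncertain_specs
            if not in_fixed and not in_unc:
                raise BundleValidationError(
                    f"bundle {self.name!r}: behavioural parameter {pname!r} absent "
                    f"from both global_fixed and global_uncertain"
                )
            if pname != "incidental_detection_rate_per_year":
                if in_fixed and not 0.0 <= float(gf[pname]) <= 1.0:
                    raise BundleValidationError(f"{pname} must lie in [0, 1]")
                if in_unc and not self.global_uncertain_specs[pname].probability:
                    raise BundleValidationError(
                        f"{pname} is probability-valued; mark its spec probability: true"
                    )
        self._life_table = LifeTable.from_dict(gf["life_table"])

    # -- resolution across the fixed/uncertain layers ------------------------
    def value(self, name: str, draw: "GlobalUncertainDraw | None" = None) -> float:
        """Resolve a scalar parameter: realized draw first, then global fixed."""
        if draw is not None and name in draw:
            return draw[name]
        if name in self.global_fixed:
            return float(self.global_fixed[name])
        raise KeyError(name)

    def cost(self, item: str, draw: "GlobalUncertainDraw | None" = None) -> float:
        """Unit cost for ``item``; an uncertain spec ``cost_<item>`` overrides."""
        if draw is not None and f"cost_{item}" in draw:
            return draw[f"cost_{item}"]
        return float(self.global_fixed["costs"][item])

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "notes": copy.deepcopy(self.notes),
            "global_fixed": copy.deepcopy(self.global_fixed),
            "global_uncertain": {
                k: v.to_dict() for k, v in sorted(self.global_uncertain_specs.items())
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterBundle":
        unknown = [k for k in d if k not in _TOP_KEYS]
        if unknown:
            raise BundleValidationError(f"unknown top-level keys: {unknown}")
        if "global_fixed" not in d:
            raise BundleValidationError("missing top-level key 'global_fixed'")
        specs = {
            name: DistributionSpec.from_dict(name, spec)
            for name, spec in (d.get("global_uncertain") or {}).items()
        }
        return cls(
            name=str(d.get("name", "unnamed")),
            global_fixed=copy.deepcopy(dict(d["global_fixed"])),
            global_uncertain_specs=specs,
            notes=copy.deepcopy(dict(d.get("notes") or {})),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterBundle):
            return NotImplemented
        return self.to_dict() == other.to_dict()


class GlobalUncertainDraw(Mapping[str, float]):
    """One realized set of global uncertain parameter values (read-only)."""

    def __init__(self, values: Mapping[str, float], draw_index: int = 0, seed=None):
        self._values = MappingProxyType(dict(values))
        self.draw_index = int(draw_index)
        self.seed = seed

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        return f"GlobalUncertainDraw({dict(self._values)!r}, draw_index={self.draw_index})"


def builtin_bundle_names() -> list[str]:
    root = resources.files("aaasim") / "bundles"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir() if p.name.endswith(".yaml"))


def load_bundle(path_or_name: str | Path) -> ParameterBundle:
    """Load and validate a parameter bundle from a YAML file.

    ``path_or_name`` may be a filesystem path or the name of a packaged
    fixture bundle (``mass-validation`` or ``naaasp-basecase``).
    """
    p = Path(path_or_name)
    if p.exists():
        text = p.read_text()
    else:
        res = resources.files("aaasim") / "bundles" / f"{path_or_name}.yaml"
        if not res.is_file():
            raise FileNotFoundError(
                f"no such bundle file or builtin bundle: {path_or_name!r} "
                f"(builtins: {builtin_bundle_names()})"
            )
        text = res.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise BundleValidationError("bundle file must contain a mapping")
    return ParameterBundle.from_dict(data)


def save_bundle(bundle: ParameterBundle, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(bundle.to_dict(), sort_keys=False))


def draw_global_uncertain(bundle: ParameterBundle, seed, draw_index: int = 0) -> GlobalUncertainDraw:
    """Draw one realization of every global uncertain parameter.

    ``seed`` may be an int or a numpy SeedSequence; identical seed and specs
    give identical draws.  Parameters are drawn in sorted-name order so the
    mapping is stable under unrelated additions elsewhere in the bundle.
    """
    rng = np.random.default_rng(seed)
    values = {
        name: bundle.global_uncertain_specs[name].draw(rng)
        for name in sorted(bundle.global_uncertain_specs)
    }
    return GlobalUncertainDraw(values, draw_index=draw_index, seed=seed)


def fix_bundle_at_means(bundle: ParameterBundle) -> GlobalUncertainDraw:
    """Deterministic 'draw' with every uncertain parameter at its distribution mean."""
    values = {
        name: spec.mean() for name, spec in sorted(bundle.global_uncertain_specs.items())
    }
    return GlobalUncertainDraw(values, draw_index=-1, seed=None)
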