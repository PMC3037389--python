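"""Model configuration: packaged defaults, TOML overrides, validation.

The packaged file ``data/defaults.toml`` is the single source of truth for
default parameter values; each key there carries a provenance comment
(``paper`` vs ``calibrated``).  ``load_config`` reads a user TOML file with
the same (flat, scalar) key layout; missing keys fall back to the defaults
and unknown keys are an error.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any

from .model import (
    CyclinRateParams,
    CyclinRates,
    ExitCondition,
    StateSpec,
    default_state_table,
    effective_rates,
)

__all__ = ["ContactInhibitionParams", "ModelConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class ContactInhibitionParams:
    """Density-dependent G1a-exit parameters for the confluence simulation."""

    p0: float = 0.5          # maximal G1a exit rate, 1/h
    n_half: float = 11000.0  # population size at half-maximal inhibition (N0)
    n_width: float = 500.0   # transition width (N1)
    n_init: int = 500        # starting cell count
    days: int = 10
    hard_cap: int = 200_000  # abort guard against runaway growth

    def validate(self) -> None:
        if self.p0 <= 0:
            raise ValueError("p0 must be > 0")
        if not 0 < self.n_width < self.n_half:
            raise ValueError("need 0 < n_width < n_half (N1 << N0)")
        if self.n_init < 1 or self.days < 0:
            raise ValueError("n_init >= 1 and days >= 0 required")


@dataclass(frozen=True)
class ModelConfig:
    """Complete, validated parameterization of the simulator."""

    rate_params: CyclinRateParams
    states: tuple[StateSpec, ...]
    thresholds: dict[str, float]
    gamma: float
    growth_mode: str = "exponential"
    delta_mean: float = 0.5
    delta_sd: float = 0.0167
    delta_clip: tuple[float, float] = (0.1, 0.9)
    threshold_sd: float = 0.033
    dna_sd: float = 0.03
    cyclin_sd: float = 0.15
    initial_conc: tuple[float, float, float] = (1.0, 1.0, 1.0)  # [CycA],[CycB],[CycE]
    initial_mass: float = 3.0
    contact_inhibition: ContactInhibitionParams = field(default_factory=ContactInhibitionParams)
    provenance: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        errors: list[str] = []
        if self.gamma <= 0:
            errors.append(f"growth.gamma must be > 0 (got {self.gamma})")
        if self.growth_mode not in ("exponential", "linear"):
            errors.append(f"growth.mode must be exponential|linear (got {self.growth_mode!r})")
        for name in ("delta_sd", "threshold_sd", "dna_sd", "cyclin_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if not 0 < self.delta_clip[0] < self.delta_mean < self.delta_clip[1] < 1:
            errors.append(f"delta clip window {self.delta_clip} must straddle the mean inside (0,1)")
        for key, theta in self.thresholds.items():
            if theta <= 0:
                errors.append(f"thresholds.{key} must be > 0 (got {theta})")
        if len(self.states) != 9 or sorted(s.index for s in self.states) != list(range(1, 10)):
            errors.append("states must cover indices 1..9 exactly once")
        else:
            for s in self.states:
                if s.exit_condition is ExitCondition.THRESHOLD:
                    if s.threshold.theta_key not in self.thresholds:
                        errors.append(f"state {s.index}: unknown threshold key {s.threshold.theta_key!r}")
                # kd > 0 in every state for every cyclin (Eq-4-style solution needs it)
                for cyc in "ABE":
                    try:
                        effective_rates(cyc, s.regulators, self.rate_params)
                    except ValueError as exc:
                        errors.append(str(exc))
        if any(c <= 0 for c in self.initial_conc) or self.initial_mass <= 0:
            errors.append("initial concentrations and mass must be > 0")
        self.contact_inhibition.validate()
        if errors:
            raise ValueError("invalid model configuration:\n  " + "\n  ".join(errors))

    # -- derived, cached ----------------------------------------------------
    def compiled_states(self) -> list[dict[str, Any]]:
        """Per-state effective rates resolved once for the simulation loops."""
        out = []
        for s in sorted(self.states, key=lambda s: s.index):
            ksa, kda = effective_rates("A", s.regulators, self.rate_params)
            ksb, kdb = effective_rates("B", s.regulators, self.rate_params)
            kse, kde = effective_rates("E", s.regulators, self.rate_params)
            out.append({
                "spec": s,
                "rates": {"A": (ksa, kda), "B": (ksb, kdb), "E": (kse, kde)},
                "theta": (self.thresholds[s.threshold.theta_key]
                          if s.exit_condition is ExitCondition.THRESHOLD else None),
            })
        return out

    def with_overrides(self, **kwargs: Any) -> "ModelConfig":
        """Functional update (re-validates)."""
        return replace(self, **kwargs)

    def deterministic(self) -> "ModelConfig":
        """Fully deterministic variant: all waiting times, division asymmetry,
        threshold noise and instrument noise disabled.  Two runs with any
        seeds produce identical output."""
        states = tuple(replace(s, lam=0.0) for s in self.states)
        return replace(self, states=states, delta_sd=0.0,
                       threshold_sd=0.0, dna_sd=0.0, cyclin_sd=0.0)

    def flat_dict(self) -> dict[str, Any]:
        """Flat key/value snapshot (manifest + round-tripping)."""
        d: dict[str, Any] = {}
        for cyc, r in (("cyclin_a", self.rate_params.a),
                       ("cyclin_b", self.rate_params.b),
                       ("cyclin_e", self.rate_params.e)):
            for k in ("ks_basal", "ks_tfe", "ks_tfb", "kd_basal",
                      "kd_scf", "kd_cdc20a", "kd_cdc20b", "kd_cdh1"):
                d[f"rates.{cyc}.{k}"] = getattr(r, k)
        for k, v in self.thresholds.items():
            d[f"thresholds.{k}"] = v
        d["states.lambdas"] = [s.lam for s in sorted(self.states, key=lambda s: s.index)]
        d["states.t_det_s"] = next(s.t_det for s in self.states if s.index == 4)
        d["growth.gamma"] = self.gamma
        d["growth.mode"] = self.growth_mode
        d["division.delta_mean"] = self.delta_mean
        d["division.delta_sd"] = self.delta_sd
        d["division.delta_clip_lo"] = self.delta_clip[0]
        d["division.delta_clip_hi"] = self.delta_clip[1]
        d["noise.threshold_sd"] = self.threshold_sd
        d["noise.dna_sd"] = self.dna_sd
        d["noise.cyclin_sd"] = self.cyclin_sd
        d["initial.cyc_a"], d["initial.cyc_b"], d["initial.cyc_e"] = self.initial_conc
        d["initial.mass"] = self.initial_mass
        ci = self.contact_inhibition
        for k in ("p0", "n_half", "n_width", "n_init", "days", "hard_cap"):
            d[f"contact_inhibition.{k}"] = getattr(ci, k)
        return d


# ---------------------------------------------------------------------------
# TOML loading

_RATE_KEYS = {"ks_basal", "ks_tfe", "ks_tfb", "kd_basal",
              "kd_scf", "kd_cdc20a", "kd_cdc20b", "kd_cdh1"}


def _read_defaults() -> dict[str, Any]:
    text = resources.files("hybridcycle").joinpath("data/defaults.toml").read_text()
    return tomllib.loads(text)


def _merge(defaults: dict[str, Any], overrides: dict[str, Any], path: str = "") -> dict[str, Any]:
    out = dict(defaults)
    for key, val in overrides.items():
        here = f"{path}{key}"
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"configuration key {here!r} must be a table")
            out[key] = _merge(defaults[key], val, here + ".")
        else:
            out[key] = val
    return out


def _build(doc: dict[str, Any]) -> ModelConfig:
    def rates(section: dict[str, Any]) -> CyclinRates:
        extra = set(section) - _RATE_KEYS
        if extra:
            raise ValueError(f"unknown rate keys: {sorted(extra)}")
        return CyclinRates(**section)

    params = CyclinRateParams(
        a=rates(doc["rates"]["cyclin_a"]),
        b=rates(doc["rates"]["cyclin_b"]),
        e=rates(doc["rates"]["cyclin_e"]),
    )
    lambdas = [float(x) for x in doc["states"]["lambdas"]]
    states = tuple(default_state_table(lambdas, t_det_s=float(doc["states"]["t_det_s"])))
    div = doc["division"]
    noise = doc["noise"]
    init = doc["initial"]
    ci = doc["contact_inhibition"]
    return ModelConfig(
        rate_params=params,
        states=states,
        thresholds={k: float(v) for k, v in doc["thresholds"].items()},
        gamma=float(doc["growth"]["gamma"]),
        growth_mode=str(doc["growth"]["mode"]),
        delta_mean=float(div["delta_mean"]),
        delta_sd=float(div["delta_sd"]),
        delta_clip=(float(div["delta_clip_lo"]), float(div["delta_clip_hi"])),
        threshold_sd=float(noise["threshold_sd"]),
        dna_sd=float(noise["dna_sd"]),
        cyclin_sd=float(noise["cyclin_sd"]),
        initial_conc=(float(init["cyc_a"]), float(init["cyc_b"]), float(init["cyc_e"])),
        initial_mass=float(init["mass"]),
        contact_inhibition=ContactInhibitionParams(
            p0=float(ci["p0"]), n_half=float(ci["n_half"]), n_width=float(ci["n_width"]),
            n_init=int(ci["n_init"]), days=int(ci["days"]), hard_cap=int(ci["hard_cap"]),
        ),
    )


def default_config() -> ModelConfig:
    """The packaged default configuration."""
    return _build(_read_defaults())


def load_config(path: str | None = None) -> ModelConfig:
    """Load a configuration file, filling missing keys from packaged defaults.

    ``path=None`` (or an empty file) returns the defaults.  Unknown keys and
    invariant violations raise ``ValueError`` naming the offending keys.
    """
    defaults = _read_defaults()
    if path is None:
        return _build(defaults)
    with open(path, "rb") as fh:
        overrides = tomllib.load(fh)
    return _build(_merge(defaults, overrides))


def gamma_for_doubling_time(hours: float) -> float:
    """Specific growth rate giving the requested mass doubling time."""
    if hours <= 0:
        raise ValueError("doubling time must be > 0")
    return math.log(2.0) / hours
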