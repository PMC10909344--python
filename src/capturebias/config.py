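"""Scenario configuration and seed management.

A :class:`ScenarioConfig` holds every tunable parameter of a simulation
run.  Defaults reproduce the reference scenario: a diploid population of
5,000 hosts with a single biallelic resistance locus, infection risks of
0.8/0.2 for the high/low-risk genotype classes, a Poisson fecundity of 10
offspring per breeding pair, and five robust-design sampling bouts of 500
captures each.

Randomness is organised around one master seed.  Each (run, stage) pair
gets its own independent ``numpy`` bit-generator derived through a keyed
``SeedSequence`` spawn, so any stage of any run can be replayed in
isolation and adding a new stage never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "SCHEMES",
    "STAGES",
    "stage_rng",
    "load_config",
    "save_config",
]

#: Recognised genotype-risk schemes.
SCHEMES = ("heterozygote_advantage", "resistance_allele")

#: Named simulation stages, each with its own child random stream.
STAGES = (
    "founders",
    "infect_parents",
    "pairing",
    "reproduction",
    "infect_offspring",
    "sample_control",
    "sample_increased",
    "sample_decreased",
    "bias_draws",
    "perturb",
)

_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}


class ConfigError(ValueError):
    """Raised for out-of-range or inconsistent scenario parameters."""


@dataclass(frozen=True)
class ScenarioConfig:
    """All tunable parameters of one simulation scenario.

    Parameters
    ----------
    population_size
        Number of founder individuals (must be even; founders are
        exhaustively paired into ``population_size / 2`` breeding pairs).
    sample_size
        Individuals captured per sampling bout.
    n_bouts
        Number of robust-design sampling bouts.
    scheme
        ``"heterozygote_advantage"`` (heterozygotes carry the low
        infection risk) or ``"resistance_allele"`` (any carrier of the
        focal allele carries the low risk).
    high_risk_prob, low_risk_prob
        Genotype-determined infection risks for the susceptible and
        resistant genotype classes.
    genotype_prediction_value
        Weight ``w`` in [0, 1] mixing genotype risk with the individual
        random risk component: ``P(infection) = clamp(w*g + (1-w)*r, 0, 1)``.
    noise_mean, noise_sd
        Parameters of the per-individual Normal random risk component.
    base_lambda
        Expected Poisson offspring per uninfected breeding pair.
    infection_penalty
        Multiplier in [0, 1] applied to an infected parent's half of the
        pair's expected offspring.  Interpreted as the *retained*
        proportion (1.0 means infection is cost-free); set
        ``penalty_is_loss=True`` to interpret it as the proportion lost.
        The default 0.0 — an infected parent's share is lost entirely —
        is the reference scenario for the experiments that perturb the
        genotype prediction weight; fitness experiments redraw it
        uniformly per run.
    n_runs
        Replicate runs per experiment.
    bias_low_range, bias_high_range
        Uniform supports for the decreased / increased capture-bias
        multiplier draws.
    seed
        Master seed for all random streams.
    rounding
        ``"half_up"`` or ``"half_even"``: how the single-infected-parent
        fecundity term ``penalty * base_lambda / 2`` is rounded.
    penalty_is_loss
        Reinterpret ``infection_penalty`` as the proportion of offspring
        lost rather than retained.
    require_parent_detected
        If True (default), sampled reproductive-success metrics use only
        parents detected in at least one bout, mirroring a field study
        where a parent must be encountered to enter the comparison; set
        False to treat every parent as enumerable with only offspring
        detection imperfect.
    """

    population_size: int = 5000
    sample_size: int = 500
    n_bouts: int = 5
    scheme: str = "heterozygote_advantage"
    high_risk_prob: float = 0.8
    low_risk_prob: float = 0.2
    genotype_prediction_value: float = 0.5
    noise_mean: float = 0.5
    noise_sd: float = 0.2
    base_lambda: float = 10.0
    infection_penalty: float = 0.0
    n_runs: int = 200
    bias_low_range: tuple[float, float] = (0.1, 0.9)
    bias_high_range: tuple[float, float] = (1.1, 1.9)
    seed: int = 0
    rounding: str = "half_up"
    penalty_is_loss: bool = False
    require_parent_detected: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be at least 2")
        if self.population_size % 2:
            raise ConfigError(
                "population_size must be even (founders are exhaustively paired)"
            )
        if not 0 < self.sample_size <= self.population_size:
            raise ConfigError("sample_size must be in (0, population_size]")
        if self.n_bouts < 1:
            raise ConfigError("n_bouts must be positive")
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        for name in ("high_risk_prob", "low_risk_prob", "genotype_prediction_value",
                     "infection_penalty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.high_risk_prob <= self.low_risk_prob:
            raise ConfigError("high_risk_prob must exceed low_risk_prob")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.base_lambda <= 0:
            raise ConfigError("base_lambda must be positive")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be positive")
        for name in ("bias_low_range", "bias_high_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name}={(lo, hi)} must satisfy 0 < low <= high")
        if self.rounding not in ("half_up", "half_even"):
            raise ConfigError("rounding must be 'half_up' or 'half_even'")

    @property
    def effective_penalty(self) -> float:
        """Retained-proportion penalty, honouring ``penalty_is_loss``."""
        return 1.0 - self.infection_penalty if self.penalty_is_loss else self.infection_penalty

    def replace(self, **changes: Any) -> "ScenarioConfig":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["bias_low_range"] = list(d["bias_low_range"])
        d["bias_high_range"] = list(d["bias_high_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("bias_low_range", "bias_high_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def stage_rng(seed: int, run_index: int, stage: str) -> np.random.Generator:
    """Independent random stream for one stage of one run.

    The stream is keyed on ``(run_index, stage)`` so stages are
    independently replayable and mutually independent.
    """
    key = (run_index, _STAGE_INDEX[stage])
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a YAML/JSON scenario file; absent keys take the defaults.

    An empty file yields the full default scenario.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as flat YAML (also valid for :func:`load_config`)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def config_to_json(config: ScenarioConfig) -> str:
    return json.dumps(config.to_dict(), indent=2)
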