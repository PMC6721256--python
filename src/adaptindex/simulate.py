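"""Synthetic cohorts with known ground-truth adaptedness.

The generator encodes the two qualitative criteria the index is built on:
an adapted organism (latent adaptedness θ ∈ [0, 1]) shows *smaller*
homeostatic shifts under the load together with *stronger* activation of its
adaptive mechanisms, and *faster* recovery toward the pre-load state.

Per subject and parameter (all effects multiplicative, so θ acts scale-free
across parameters of very different magnitudes):

* pre-load      ``K′ ~ Normal(μ, σ)``
* homeostatic   ``K″ = K′ · (1 + δ·(1 − θ) + ε)``
* adaptive      ``K″ = K′ · (1 + γ·θ + ε)``
* recovery      ``K‴ = K″ + ρ(θ)·(1 + η)·(K′ − K″)``,  ρ(θ) = ρ0 + ρ1·θ

with ε ~ Normal(0, load_noise_sd) and η ~ Normal(0, recovery_noise_sd).
Recovery noise perturbs the recovery *rate* rather than the level: this
emulates a well-designed protocol in which the rest interval is chosen so
the recovery step is always resolvable (the recovery fraction then equals
``|1 − ρ(1 + η)| / (ρ(1 + η))`` and stays bounded), whereas additive level
noise would let the fraction's denominator cross zero and give the index
heavy-tailed, effectively unusable recovery terms — the very situation the
method demands the experimenter avoid by choice of Δt.  Generated values
are clipped at 1% of the baseline mean to preserve positivity (clip events
are counted).  Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Category, ParameterSpec, ParamStates, SubjectProfile
from .errors import ConfigError

__all__ = [
    "ParameterSim",
    "GroupSim",
    "SimulationConfig",
    "SimulatedStudy",
    "default_panel",
    "default_config",
    "simulate_cohort",
    "simulate_study",
]


@dataclass(frozen=True)
class ParameterSim:
    """Generating model for one parameter.

    ``load_effect`` (δ) is the relative homeostatic shift of a completely
    unadapted subject; ``adaptive_gain`` (γ) the relative activation of an
    adaptive parameter at full adaptedness.  Only the field matching the
    category is used; indifferent parameters ignore both.
    """

    name: str
    category: Category
    baseline_mean: float
    baseline_sd: float = 0.0
    load_effect: float = 0.5
    adaptive_gain: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category.parse(self.category))
        if self.baseline_mean <= 0:
            raise ConfigError(f"parameter {self.name!r}: baseline mean must be > 0")
        if self.baseline_sd < 0 or self.load_effect < 0 or self.adaptive_gain < 0:
            raise ConfigError(f"parameter {self.name!r}: negative effect/sd field")

    @property
    def spec(self) -> ParameterSpec:
        return ParameterSpec(self.name, self.category)


@dataclass(frozen=True)
class GroupSim:
    group_id: str
    theta: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ConfigError(
                f"group {self.group_id!r}: theta must lie in [0, 1], got {self.theta}"
            )
        if self.n < 1:
            raise ConfigError(f"group {self.group_id!r}: n must be >= 1")


@dataclass
class SimulationConfig:
    """Full description of a simulated study."""

    parameters: list[ParameterSim]
    groups: list[GroupSim]
    rho0: float = 0.5
    rho1: float = 0.4
    load_noise_sd: float = 0.05
    recovery_noise_sd: float = 0.02
    include_recovery: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        problems = []
        if not self.parameters:
            problems.append("no parameters configured")
        if not self.groups:
            problems.append("no groups configured")
        if self.rho0 < 0 or self.rho1 < 0:
            problems.append("rho0 and rho1 must be >= 0")
        for g in self.groups:
            if not (0.0 <= self.rho(g.theta) <= 1.0):
                problems.append(
                    f"rho(theta={g.theta}) = {self.rho(g.theta):.3f} outside [0, 1]"
                )
        if self.load_noise_sd < 0 or self.recovery_noise_sd < 0:
            problems.append("noise sds must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))

    def rho(self, theta: float) -> float:
        return self.rho0 + self.rho1 * theta

    @property
    def specs(self) -> list[ParameterSpec]:
        return [p.spec for p in self.parameters]


@dataclass
class SimulatedStudy:
    """A generated Case II dataset plus its ground truth."""

    profiles: list[SubjectProfile]
    theta: dict[str, float]
    clip_events: int = 0

    @property
    def true_ordering(self) -> list[str]:
        """Group ids from most to least adapted (descending θ)."""
        return sorted(self.theta, key=lambda g: -self.theta[g])


def default_panel() -> list[ParameterSim]:
    """A realistic exercise-biochemistry panel: one adaptive stress hormone
    plus four homeostatic substrates/metabolites with ~10% baseline CV."""
    return [
        ParameterSim("stress_hormone", Category.ADAPTIVE, 12.0, 1.2, adaptive_gain=1.5),
        ParameterSim("glycolytic_enzyme", Category.HOMEOSTATIC, 14.0, 1.4, load_effect=0.5),
        ParameterSim("lactate", Category.HOMEOSTATIC, 6.0, 0.6, load_effect=0.6),
        ParameterSim("ammonia", Category.HOMEOSTATIC, 100.0, 10.0, load_effect=0.4),
        ParameterSim("glycogen", Category.HOMEOSTATIC, 700.0, 70.0, load_effect=0.3),
    ]


def default_config(
    thetas: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    n: int = 25,
    seed: int | None = None,
    include_recovery: bool = True,
) -> SimulationConfig:
    groups = [GroupSim(f"g{i + 1}", t, n) for i, t in enumerate(thetas)]
    return SimulationConfig(
        parameters=default_panel(),
        groups=groups,
        seed=seed,
        include_recovery=include_recovery,
    )


def _simulate_group(
    config: SimulationConfig, group: GroupSim, rng: np.random.Generator
) -> tuple[list[SubjectProfile], int]:
    clips = 0
    profiles = []
    rho = config.rho(group.theta)
    for i in range(group.n):
        values: dict[str, ParamStates] = {}
        for p in config.parameters:
            floor = 0.01 * p.baseline_mean
            pre = float(rng.normal(p.baseline_mean, p.baseline_sd))
            if pre < floor:
                pre, clips = floor, clips + 1
            eps = float(rng.normal(0.0, config.load_noise_sd)) if config.load_noise_sd else 0.0
            if p.category is Category.HOMEOSTATIC:
                factor = 1.0 + p.load_effect * (1.0 - group.theta) + eps
            elif p.category is Category.ADAPTIVE:
                factor = 1.0 + p.adaptive_gain * group.theta + eps
            else:
                factor = 1.0 + eps
            load = pre * factor
            if load < floor:
                load, clips = floor, clips + 1
            rec: float | None = None
            if config.include_recovery:
                eta = (
                    float(rng.normal(0.0, config.recovery_noise_sd))
                    if config.recovery_noise_sd
                    else 0.0
                )
                rec = load + rho * (1.0 + eta) * (pre - load)
                if rec < floor:
                    rec, clips = floor, clips + 1
            values[p.name] = ParamStates(pre=pre, load=load, rec=rec)
        profiles.append(
            SubjectProfile(
                subject_id=f"{group.group_id}-{i + 1:03d}",
                group_id=group.group_id,
                values=values,
            )
        )
    return profiles, clips


def simulate_cohort(config: SimulationConfig, group: GroupSim | str) -> list[SubjectProfile]:
    """Generate one group's profiles (deterministic under ``config.seed``).

    The per-group random stream is derived from the config seed and the
    group's position, so a group's data do not depend on how many other
    groups are simulated before it.
    """
    if isinstance(group, str):
        matches = [g for g in config.groups if g.group_id == group]
        if not matches:
            raise ConfigError(f"unknown group {group!r}")
        group = matches[0]
    index = config.groups.index(group)
    rng = np.random.default_rng(
        None if config.seed is None else (config.seed, index)
    )
    profiles, _ = _simulate_group(config, group, rng)
    return profiles


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full Case II dataset plus its ground-truth θ ordering."""
    if len(config.groups) < 2:
        raise ConfigError("a study needs at least 2 groups")
    profiles: list[SubjectProfile] = []
    clips = 0
    for index, group in enumerate(config.groups):
        rng = np.random.default_rng(
            None if config.seed is None else (config.seed, index)
        )
        group_profiles, group_clips = _simulate_group(config, group, rng)
        profiles.extend(group_profiles)
        clips += group_clips
    return SimulatedStudy(
        profiles=profiles,
        theta={g.group_id: g.theta for g in config.groups},
        clip_events=clips,
    )
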