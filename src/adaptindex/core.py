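"""Per-parameter and per-subject adaptedness index mathematics.

The index scores how well a regulating (homeostatic) organism withstands an
acute provoking load Q, optionally after a chronic conditioning factor P
(training, adaptogen pre-treatment).  Each physiological parameter K is
measured at up to four states:

* ``F0`` — intact baseline, before P (used only to estimate stability),
* ``F1`` — pre-load, after P but before Q (written K′),
* ``F2`` — immediately after Q (K″),
* ``F3`` — after a rest interval Δt (K‴, optional).

Two dimensionless fractions summarise each parameter's behaviour:

* response fraction ``|K″ − K′| / K′`` — relative shift under the load;
* recovery fraction ``|K‴ − K′| / |K‴ − K″|`` — small when the parameter
  returned quickly toward its pre-load value during rest.

Parameters are user-classified as *homeostatic* (shift directly under the
load; smaller shifts mean better adaptedness, so their response enters with a
minus sign), *adaptive* (compensatory/allostatic mechanisms such as heart
rate or corticosteroid output; stronger activation is favourable, plus sign),
or *indifferent* (contribute zero).  Recovery fractions are always
subtracted.  Each term may additionally be weighted by the parameter's
stability coefficient ``S = 1 − SD/mean`` computed on an intact baseline
cohort: changes in tightly regulated (low-variability) parameters carry more
weight than changes in labile ones.

The subject-level index is

    a = Σ_j S_j (−resp_j − rec_j)  +  Σ_h S_h (+resp_h − rec_h)

over the m homeostatic (j) and d adaptive (h) parameters, with S ≡ 1 in the
unweighted mode.  Indices are only comparable between subjects or groups
measured on identical parameter sets with identical options.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import (
    ConfigError,
    DataError,
    InvalidReferenceError,
    LowStabilityWarning,
    NonApplicableDistributionError,
    ParadoxicalChangeWarning,
    RecoveryIntervalError,
    SlowRecoveryWarning,
    ValidationError,
)

__all__ = [
    "Category",
    "State",
    "ParameterSpec",
    "StabilityEntry",
    "StabilityTable",
    "ParamStates",
    "SubjectProfile",
    "IndexOptions",
    "TermBreakdown",
    "AdaptednessResult",
    "ValidationReport",
    "response_fraction",
    "recovery_fraction",
    "stability_coefficient",
    "signed_term",
    "subject_index",
    "validate_inputs",
]

#: Minimum stability coefficient the model considers well calibrated.
LOW_STABILITY_THRESHOLD = 0.5


class Category(str, enum.Enum):
    """Role of a parameter in the index."""

    HOMEOSTATIC = "homeostatic"
    ADAPTIVE = "adaptive"
    INDIFFERENT = "indifferent"

    @classmethod
    def parse(cls, value: "Category | str") -> "Category":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ConfigError(
                f"unknown parameter category {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


class State(str, enum.Enum):
    """Measurement state labels with their file-format synonyms."""

    BASELINE = "F0"
    PRE_LOAD = "F1"
    POST_LOAD = "F2"
    RECOVERY = "F3"

    @classmethod
    def parse(cls, value: "State | str") -> "State":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        synonyms = {
            "f0": cls.BASELINE,
            "baseline": cls.BASELINE,
            "f1": cls.PRE_LOAD,
            "pre": cls.PRE_LOAD,
            "f2": cls.POST_LOAD,
            "load": cls.POST_LOAD,
            "f3": cls.RECOVERY,
            "recovery": cls.RECOVERY,
        }
        if key not in synonyms:
            raise DataError(
                f"unknown state label {value!r}; expected one of "
                "F0/F1/F2/F3 or baseline/pre/load/recovery"
            )
        return synonyms[key]


@dataclass(frozen=True)
class ParameterSpec:
    """A measured variable: its name, category and (free-text) units.

    The category is the sign carrier of the index: homeostatic responses
    enter negatively, adaptive responses positively, indifferent parameters
    contribute exactly zero.  It is immutable within one analysis.
    """

    name: str
    category: Category
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category.parse(self.category))


@dataclass(frozen=True)
class StabilityEntry:
    """One parameter's stability weight S with provenance.

    ``provenance`` is ``"computed"`` when S was derived from a baseline
    cohort (``source`` then describes group, state and n) or ``"supplied"``
    when taken as printed/configured.
    """

    S: float
    provenance: str = "supplied"
    source: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.S <= 1.0):
            raise ConfigError(f"stability coefficient must lie in (0, 1], got {self.S}")


class StabilityTable(Mapping[str, StabilityEntry]):
    """Per-parameter stability coefficients.

    Behaves as a read-only mapping from parameter name to
    :class:`StabilityEntry`.  Entries with S < 0.5 are permitted but trigger
    a :class:`~adaptindex.errors.LowStabilityWarning` on construction.
    """

    def __init__(self, entries: Mapping[str, StabilityEntry | float], *, warn: bool = True):
        self._entries: dict[str, StabilityEntry] = {}
        for name, entry in entries.items():
            if not isinstance(entry, StabilityEntry):
                entry = StabilityEntry(float(entry))
            self._entries[str(name)] = entry
        if warn:
            low = [n for n, e in self._entries.items() if e.S < LOW_STABILITY_THRESHOLD]
            if low:
                warnings.warn(
                    f"stability coefficient below {LOW_STABILITY_THRESHOLD} for "
                    f"{', '.join(low)}; the weighting may be poorly calibrated",
                    LowStabilityWarning,
                    stacklevel=2,
                )

    @classmethod
    def from_baseline(
        cls,
        values_by_parameter: Mapping[str, Sequence[float]],
        *,
        source: str | None = None,
    ) -> "StabilityTable":
        """Compute S for each parameter from a baseline cohort's raw values."""
        entries = {
            name: StabilityEntry(
                stability_coefficient(vals),
                provenance="computed",
                source=f"{source or 'baseline'} (n={len(vals)})",
            )
            for name, vals in values_by_parameter.items()
        }
        return cls(entries)

    @classmethod
    def from_summaries(
        cls,
        summaries: Mapping[str, tuple[float, float]],
        *,
        source: str | None = None,
    ) -> "StabilityTable":
        """Compute S from per-parameter (mean, sd) baseline summaries."""
        entries = {
            name: StabilityEntry(
                stability_coefficient(mean=mean, sd=sd),
                provenance="computed",
                source=source or "baseline summary",
            )
            for name, (mean, sd) in summaries.items()
        }
        return cls(entries)

    def __getitem__(self, name: str) -> StabilityEntry:
        return self._entries[name]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}={e.S:.3f}" for n, e in self._entries.items())
        return f"StabilityTable({inner})"


@dataclass(frozen=True)
class ParamStates:
    """One parameter's values at the states used by the index.

    ``baseline`` (F0) is carried only for stability estimation; ``rec`` (F3)
    is optional and must be present or absent uniformly within a profile.
    """

    pre: float
    load: float
    rec: float | None = None
    baseline: float | None = None


@dataclass
class SubjectProfile:
    """A single subject's measurements across states.

    ``significant`` optionally marks, per parameter, whether the F1→F2
    change is statistically significant; parameters marked ``False`` have
    their response fraction taken for zero (the paradoxical-change rule).
    """

    subject_id: str
    group_id: str
    values: dict[str, ParamStates]
    significant: dict[str, bool] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def has_recovery(self) -> bool:
        return any(ps.rec is not None for ps in self.values.values())

    def with_mask(self, significant: Mapping[str, bool]) -> "SubjectProfile":
        """Return a copy carrying the given significance mask."""
        mask = dict(self.significant or {})
        mask.update(significant)
        return replace(self, significant=mask)


@dataclass(frozen=True)
class IndexOptions:
    """Analysis options; results are only comparable under one fingerprint.

    weighting
        ``"stability"`` multiplies each parameter's term by its S weight
        (the default); ``"none"`` uses unit weights.
    include_recovery
        ``None`` (auto: include when F3 data are present), ``True`` or
        ``False``.
    recovery_cap
        Optional finite value substituted for a diverging recovery fraction
        (K‴ = K″ ≠ K′); by default such data raise an error.
    alpha
        Significance level for insignificance zeroing and pairwise tests.
    confidence
        Confidence level for group intervals.
    """

    weighting: str = "stability"
    include_recovery: bool | None = None
    recovery_cap: float | None = None
    alpha: float = 0.05
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.weighting not in ("stability", "none"):
            raise ConfigError(
                f"weighting must be 'stability' or 'none', got {self.weighting!r}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 < self.confidence < 1.0):
            raise ConfigError(f"confidence must lie in (0, 1), got {self.confidence}")
        if self.recovery_cap is not None and not (
            math.isfinite(self.recovery_cap) and self.recovery_cap > 0
        ):
            raise ConfigError("recovery_cap must be a finite positive number")

    def fingerprint(self, specs: Sequence[ParameterSpec]) -> tuple:
        """Hashable identity of the comparison context."""
        return (
            self.weighting,
            self.include_recovery,
            tuple((s.name, s.category.value) for s in specs),
        )


@dataclass(frozen=True)
class TermBreakdown:
    """One parameter's contribution to a subject's index."""

    parameter: str
    category: Category
    S: float | None
    response_fraction: float
    recovery_fraction: float | None
    weighting: str
    contribution: float
    zeroed_insignificant: bool = False


@dataclass
class AdaptednessResult:
    """A subject's index a or a group's index A, with its breakdown.

    ``value`` always equals the sum of the breakdown contributions.  Group
    results additionally carry dispersion (sd), n, a confidence interval and,
    once ranked, a rank (1 = most adaptive).
    """

    scope: str  # "subject" | "group"
    id: str
    value: float
    breakdown: list[TermBreakdown]
    options: IndexOptions
    sd: float | None = None
    n: int | None = None
    ci: tuple[float, float] | None = None
    rank: int | None = None


@dataclass
class ValidationReport:
    """Outcome of joint input validation: hard errors plus advisory flags."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_for_errors(self) -> None:
        if self.errors:
            raise ValidationError("; ".join(self.errors))


# ---------------------------------------------------------------------------
# Elementary fractions
# ---------------------------------------------------------------------------

def _check_finite(name: str, **values: float | None) -> None:
    for label, v in values.items():
        if v is not None and not math.isfinite(v):
            raise DataError(f"non-finite {label} value for parameter {name!r}: {v}")


def response_fraction(k_pre: float, k_load: float, *, parameter: str = "?") -> float:
    """Relative shift of a parameter under the load: ``|K″ − K′| / K′``.

    The modulus makes responses comparable irrespective of direction; the
    division by the pre-load value makes them comparable across parameters
    with different units and magnitudes.
    """
    _check_finite(parameter, pre=k_pre, load=k_load)
    if k_pre <= 0:
        raise InvalidReferenceError(
            f"pre-load value for parameter {parameter!r} must be positive, got {k_pre}"
        )
    return abs(k_load - k_pre) / k_pre


def recovery_fraction(
    k_pre: float,
    k_load: float,
    k_rec: float,
    *,
    parameter: str = "?",
    cap: float | None = None,
) -> float:
    """Recovery term ``|K‴ − K′| / |K‴ − K″|``.

    The numerator measures how far the parameter still is from its pre-load
    value after the rest interval; the denominator, how large the recovery
    step was.  Perfect return to baseline (K‴ = K′) yields 0 by convention —
    including the 0/0 case where the parameter never moved.  K‴ = K″ ≠ K′
    means the rest interval resolved nothing and the fraction diverges; this
    raises :class:`~adaptindex.errors.RecoveryIntervalError` unless a finite
    ``cap`` is supplied to stand in for the diverging term.
    """
    _check_finite(parameter, pre=k_pre, load=k_load, rec=k_rec)
    if k_pre <= 0:
        raise InvalidReferenceError(
            f"pre-load value for parameter {parameter!r} must be positive, got {k_pre}"
        )
    numerator = abs(k_rec - k_pre)
    if numerator == 0.0:  # full recovery wins, including 0/0
        return 0.0
    denominator = abs(k_rec - k_load)
    if denominator == 0.0:
        if cap is not None:
            return cap
        raise RecoveryIntervalError(
            f"parameter {parameter!r}: recovery value equals post-load value "
            f"({k_rec}) while differing from pre-load ({k_pre}); the recovery "
            "fraction diverges — such rest intervals should be avoided "
            "(or supply a finite recovery_cap)"
        )
    return numerator / denominator


def stability_coefficient(
    baseline_values: Sequence[float] | None = None,
    *,
    mean: float | None = None,
    sd: float | None = None,
    parameter: str = "?",
    warn: bool = True,
) -> float:
    """Stability weight ``S = 1 − SD/mean`` of a baseline cohort.

    Accepts either a raw series of ≥ 2 positive measurements (sample SD,
    n − 1 denominator) or a pre-computed (mean, sd) summary.  S close to 1
    marks tightly regulated constants (pH, body temperature); S below 0.5
    marks distributions too variable for the model and triggers a warning.
    SD ≥ mean (S ≤ 0) is rejected outright.
    """
    if baseline_values is not None:
        if mean is not None or sd is not None:
            raise ConfigError("pass either a raw series or (mean, sd), not both")
        vals = [float(v) for v in baseline_values]
        if len(vals) < 2:
            raise DataError(
                f"parameter {parameter!r}: need at least 2 baseline values, got {len(vals)}"
            )
        _check_finite(parameter, **{f"baseline[{i}]": v for i, v in enumerate(vals)})
        n = len(vals)
        mean = sum(vals) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    if mean is None or sd is None:
        raise ConfigError("either a raw series or both mean and sd are required")
    _check_finite(parameter, mean=mean, sd=sd)
    if mean <= 0:
        raise InvalidReferenceError(
            f"parameter {parameter!r}: baseline mean must be positive, got {mean}"
        )
    if sd < 0:
        raise DataError(f"parameter {parameter!r}: negative sd {sd}")
    if sd >= mean:
        raise NonApplicableDistributionError(
            f"parameter {parameter!r}: SD ({sd}) >= mean ({mean}); S would be "
            "<= 0 — such distributions are outside the model"
        )
    S = 1.0 - sd / mean
    if warn and S < LOW_STABILITY_THRESHOLD:
        warnings.warn(
            f"parameter {parameter!r}: stability coefficient {S:.3f} is below "
            f"{LOW_STABILITY_THRESHOLD}",
            LowStabilityWarning,
            stacklevel=2,
        )
    return S


# ---------------------------------------------------------------------------
# Signed terms and the subject index
# ---------------------------------------------------------------------------

def signed_term(
    spec: ParameterSpec,
    S: float | None,
    resp: float,
    rec: float | None = None,
    weighting: str = "stability",
    *,
    zeroed: bool = False,
) -> TermBreakdown:
    """Combine one parameter's fractions into its signed contribution.

    Homeostatic: ``w·(−resp − rec)`` — any shift, and any incomplete
    recovery, penalise the index.  Adaptive: ``w·(+resp − rec)`` — strong
    activation is rewarded, slow normalisation still penalised.  Indifferent
    parameters contribute exactly 0 (kept in the breakdown so the m/d
    bookkeeping stays visible).  ``w`` is S under stability weighting, 1
    otherwise; a missing recovery fraction counts as 0.
    """
    category = Category.parse(spec.category)
    if weighting not in ("stability", "none"):
        raise ConfigError(f"unknown weighting mode {weighting!r}")
    if resp < 0:
        raise DataError(f"parameter {spec.name!r}: negative response fraction {resp}")
    if rec is not None and rec < 0:
        raise DataError(f"parameter {spec.name!r}: negative recovery fraction {rec}")
    rec_term = 0.0 if rec is None else rec
    if category is Category.INDIFFERENT:
        contribution = 0.0
    else:
        if weighting == "stability":
            if S is None:
                raise ConfigError(
                    f"parameter {spec.name!r}: stability weighting requested but "
                    "no S available"
                )
            w = S
        else:
            w = 1.0
        sign = -1.0 if category is Category.HOMEOSTATIC else 1.0
        contribution = w * (sign * resp - rec_term)
    return TermBreakdown(
        parameter=spec.name,
        category=category,
        S=S,
        response_fraction=resp,
        recovery_fraction=rec,
        weighting=weighting,
        contribution=contribution,
        zeroed_insignificant=zeroed,
    )


def _resolve_recovery(options: IndexOptions, profile: SubjectProfile) -> bool:
    if options.include_recovery is None:
        return profile.has_recovery
    return options.include_recovery


def subject_index(
    profile: SubjectProfile,
    specs: Sequence[ParameterSpec],
    stability: StabilityTable | None = None,
    options: IndexOptions | None = None,
) -> AdaptednessResult:
    """Compute a subject's adaptedness index a.

    Sums the signed, optionally S-weighted terms of every parameter in
    ``specs`` order.  Parameters flagged insignificant in the profile's mask
    contribute a zero response fraction (their recovery term, if any, is kept).
    """
    options = options or IndexOptions()
    missing = [s.name for s in specs if s.name not in profile.values]
    if missing:
        raise ValidationError(
            f"subject {profile.subject_id!r}: missing parameters {missing}"
        )
    use_recovery = _resolve_recovery(options, profile)
    breakdown: list[TermBreakdown] = []
    for spec in specs:
        ps = profile.values[spec.name]
        resp = response_fraction(ps.pre, ps.load, parameter=spec.name)
        zeroed = False
        if profile.significant is not None and not profile.significant.get(spec.name, True):
            resp = 0.0
            zeroed = True
        rec: float | None = None
        if use_recovery:
            if ps.rec is None:
                raise ValidationError(
                    f"subject {profile.subject_id!r}: recovery requested but "
                    f"parameter {spec.name!r} has no F3 value"
                )
            rec = recovery_fraction(
                ps.pre, ps.load, ps.rec, parameter=spec.name, cap=options.recovery_cap
            )
        S: float | None = None
        if stability is not None and spec.name in stability:
            S = stability[spec.name].S
        elif options.weighting == "stability" and spec.category is not Category.INDIFFERENT:
            raise ConfigError(
                f"parameter {spec.name!r}: stability weighting requested but no "
                "S entry in the stability table"
            )
        breakdown.append(
            signed_term(spec, S, resp, rec, options.weighting, zeroed=zeroed)
        )
    return AdaptednessResult(
        scope="subject",
        id=profile.subject_id,
        value=sum(t.contribution for t in breakdown),
        breakdown=breakdown,
        options=options,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _category_counts(specs: Sequence[ParameterSpec]) -> tuple[int, int]:
    m = sum(1 for s in specs if s.category is Category.HOMEOSTATIC)
    d = sum(1 for s in specs if s.category is Category.ADAPTIVE)
    return m, d


def validate_inputs(
    profiles: Iterable[SubjectProfile],
    specs: Sequence[ParameterSpec],
    options: IndexOptions | None = None,
    stability: StabilityTable | None = None,
) -> ValidationReport:
    """Jointly validate profiles that are to be compared.

    Hard errors: missing parameters (which would make homeostatic/adaptive
    counts differ between compared units), non-positive pre-load references,
    non-uniform recovery availability, missing S entries under stability
    weighting.  Warnings: opposite response directions for the same parameter
    in different groups (paradoxical-change candidates), S below 0.5,
    recovery fractions above 1.
    """
    options = options or IndexOptions()
    report = ValidationReport()
    profiles = list(profiles)
    if not profiles:
        report.errors.append("no profiles supplied")
        return report

    spec_names = [s.name for s in specs]
    recovery_flags: set[bool] = set()
    directions: dict[str, dict[str, set[int]]] = {n: {} for n in spec_names}

    for p in profiles:
        missing = [n for n in spec_names if n not in p.values]
        if missing:
            report.errors.append(
                f"subject {p.subject_id!r} (group {p.group_id!r}) is missing "
                f"parameters {missing}: homeostatic/adaptive counts must match "
                "across compared units"
            )
            continue
        per_param_rec = {n: p.values[n].rec is not None for n in spec_names}
        if len(set(per_param_rec.values())) > 1:
            with_rec = sorted(n for n, v in per_param_rec.items() if v)
            without = sorted(n for n, v in per_param_rec.items() if not v)
            report.errors.append(
                f"subject {p.subject_id!r}: recovery values present for "
                f"{with_rec} but absent for {without}; recovery must be "
                "uniform within a profile"
            )
        recovery_flags.add(all(per_param_rec.values()))
        for n in spec_names:
            ps = p.values[n]
            if not math.isfinite(ps.pre) or not math.isfinite(ps.load):
                report.errors.append(
                    f"subject {p.subject_id!r}, parameter {n!r}: non-finite value"
                )
                continue
            if ps.pre <= 0:
                report.errors.append(
                    f"subject {p.subject_id!r}, parameter {n!r}: pre-load value "
                    f"{ps.pre} is not positive"
                )
                continue
            delta = ps.load - ps.pre
            if delta != 0:
                directions[n].setdefault(p.group_id, set()).add(1 if delta > 0 else -1)
            if ps.rec is not None and _resolve_recovery(options, p):
                try:
                    rec = recovery_fraction(
                        ps.pre, ps.load, ps.rec, parameter=n, cap=options.recovery_cap
                    )
                except RecoveryIntervalError as exc:
                    report.errors.append(str(exc))
                else:
                    if rec > 1.0:
                        msg = (
                            f"subject {p.subject_id!r}, parameter {n!r}: recovery "
                            f"fraction {rec:.3f} exceeds 1 (rest interval may be "
                            "too short)"
                        )
                        report.warnings.append(msg)
                        warnings.warn(msg, SlowRecoveryWarning, stacklevel=2)

    if len(recovery_flags) > 1:
        report.errors.append(
            "recovery availability differs between compared profiles; terms "
            "must be included or excluded uniformly"
        )

    for n, by_group in directions.items():
        signs = {s for group_signs in by_group.values() for s in group_signs}
        if len(by_group) > 1 and len(signs) > 1:
            per_group = {
                g: "up" if s == {1} else "down" if s == {-1} else "mixed"
                for g, s in by_group.items()
            }
            msg = (
                f"parameter {n!r} responds in opposite directions across groups "
                f"({per_group}): paradoxical-change candidate — consider the "
                "insignificance-zeroing rule"
            )
            report.warnings.append(msg)
            warnings.warn(msg, ParadoxicalChangeWarning, stacklevel=2)

    if options.weighting == "stability":
        need_S = [s.name for s in specs if s.category is not Category.INDIFFERENT]
        if stability is None:
            report.errors.append("stability weighting requested but no stability table")
        else:
            missing_S = [n for n in need_S if n not in stability]
            if missing_S:
                report.errors.append(f"missing stability entries for {missing_S}")
            for n in need_S:
                if n in stability and stability[n].S < LOW_STABILITY_THRESHOLD:
                    report.warnings.append(
                        f"parameter {n!r}: stability coefficient "
                        f"{stability[n].S:.3f} below {LOW_STABILITY_THRESHOLD}"
                    )
    return report
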