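"""The three experimental designs the index supports.

* **Case I** — two individual subjects measured repeatedly across states;
  their indices a are compared directly.
* **Case II** — two or more groups measured repeatedly (every subject yields
  its own a); group indices are the means A = ā with ordinary dispersion,
  confidence intervals and pairwise tests on the individual a values.
* **Case III** — destructive (parallel) sampling: different animals are
  killed at each state, so no individual trajectory exists.  Each parameter
  is replaced by its per-state group mean and the index is computed on the
  resulting pseudo-profile.  The dispersion of A is not defined by the
  model in this design; a parametric bootstrap over the cell means is
  provided as an extension and labelled as such in reports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    AdaptednessResult,
    IndexOptions,
    ParameterSpec,
    ParamStates,
    StabilityTable,
    State,
    SubjectProfile,
    subject_index,
    validate_inputs,
)
from .errors import (
    ConfigError,
    DataError,
    RankTieWarning,
    ValidationError,
)

__all__ = [
    "GroupCellSummary",
    "PairwiseTest",
    "GroupComparison",
    "ZeroingResult",
    "compare_subjects",
    "group_index_repeated",
    "group_index_destructive",
    "bootstrap_uncertainty",
    "zero_insignificant",
    "rank_groups",
]


@dataclass(frozen=True)
class GroupCellSummary:
    """Summary of one (group, parameter, state) cell: mean ± SD of n animals."""

    group_id: str
    parameter: str
    state: State
    mean: float
    sd: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", State.parse(self.state))
        if not math.isfinite(self.mean) or self.mean <= 0:
            raise DataError(
                f"cell ({self.group_id}, {self.parameter}, {self.state.value}): "
                f"mean must be positive and finite, got {self.mean}"
            )
        if self.sd is not None and (not math.isfinite(self.sd) or self.sd < 0):
            raise DataError(
                f"cell ({self.group_id}, {self.parameter}, {self.state.value}): "
                f"sd must be >= 0, got {self.sd}"
            )
        if self.n is not None and self.n < 1:
            raise DataError(
                f"cell ({self.group_id}, {self.parameter}, {self.state.value}): "
                f"n must be >= 1, got {self.n}"
            )


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    method: str


@dataclass
class GroupComparison:
    """Group indices A with dispersion, ranks and pairwise tests."""

    design: str
    groups: dict[str, AdaptednessResult]
    pairwise: list[PairwiseTest] = field(default_factory=list)
    fingerprint: tuple = ()
    warnings: list[str] = field(default_factory=list)

    @property
    def ranks(self) -> dict[str, int]:
        return {g: r.rank for g, r in self.groups.items() if r.rank is not None}

    @property
    def values(self) -> dict[str, float]:
        return {g: r.value for g, r in self.groups.items()}


@dataclass
class ZeroingResult:
    """Outcome of the insignificance-zeroing rule.

    ``masks`` maps group id -> parameter -> significant? (False means the
    response fraction is taken for zero); ``profiles`` carries masked copies
    when profiles were supplied.
    """

    masks: dict[str, dict[str, bool]]
    log: list[str]
    profiles: list[SubjectProfile] | None = None


# ---------------------------------------------------------------------------
# Case I
# ---------------------------------------------------------------------------

def compare_subjects(
    profile_b: SubjectProfile,
    profile_c: SubjectProfile,
    specs: Sequence[ParameterSpec],
    stability: StabilityTable | None = None,
    options: IndexOptions | None = None,
    *,
    tol: float = 1e-9,
) -> tuple[AdaptednessResult, AdaptednessResult, str]:
    """Case I: compare two subjects' indices under one shared setup.

    Returns both results and a verdict string naming the more adaptive
    subject (a larger a), or ``"equal"`` when |a_b − a_c| ≤ ``tol``.
    """
    options = options or IndexOptions()
    report = validate_inputs([profile_b, profile_c], specs, options, stability)
    report.raise_for_errors()
    res_b = subject_index(profile_b, specs, stability, options)
    res_c = subject_index(profile_c, specs, stability, options)
    if abs(res_b.value - res_c.value) <= tol:
        verdict = "equal"
    elif res_b.value > res_c.value:
        verdict = f"{profile_b.subject_id} more adaptive"
    else:
        verdict = f"{profile_c.subject_id} more adaptive"
    return res_b, res_c, verdict


# ---------------------------------------------------------------------------
# Case II
# ---------------------------------------------------------------------------

def _group_profiles(
    profiles: Iterable[SubjectProfile],
) -> dict[str, list[SubjectProfile]]:
    by_group: dict[str, list[SubjectProfile]] = {}
    for p in profiles:
        by_group.setdefault(p.group_id, []).append(p)
    return by_group


def _normal_ci(mean: float, sd: float, n: int, confidence: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    half = z * sd / math.sqrt(n)
    return (mean - half, mean + half)


def _permutation_p(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, n_perm: int
) -> tuple[float, float]:
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        diff = pooled[: a.size].mean() - pooled[a.size :].mean()
        if abs(diff) >= abs(observed) - 1e-15:
            count += 1
    return observed, (count + 1) / (n_perm + 1)


def group_index_repeated(
    profiles: Iterable[SubjectProfile],
    specs: Sequence[ParameterSpec],
    stability: StabilityTable | None = None,
    options: IndexOptions | None = None,
    *,
    test: str = "welch",
    permutations: int = 2000,
    seed: int | None = None,
    dispersion: bool | None = None,
) -> GroupComparison:
    """Case II: group indices A as means of individual indices a.

    A group's A is the arithmetic mean of its subjects' a values (the 1/n
    factor matters whenever group sizes differ).  Dispersion is the sample
    SD of the a values with a normal-approximation confidence interval;
    ``dispersion=None`` computes it when every group has at least two
    subjects.  Pairwise group differences are tested with Welch's t on the
    individual a values, or a seeded label-permutation test for small n.
    """
    options = options or IndexOptions()
    profiles = list(profiles)
    report = validate_inputs(profiles, specs, options, stability)
    report.raise_for_errors()
    by_group = _group_profiles(profiles)
    if dispersion is None:
        dispersion = all(len(ps) >= 2 for ps in by_group.values())
    comparison_warnings = list(report.warnings)

    a_values: dict[str, np.ndarray] = {}
    groups: dict[str, AdaptednessResult] = {}
    for gid, members in by_group.items():
        results = [subject_index(p, specs, stability, options) for p in members]
        vals = np.array([r.value for r in results], dtype=float)
        a_values[gid] = vals
        n = vals.size
        sd = ci = None
        if dispersion:
            if n < 2:
                raise ValidationError(
                    f"group {gid!r}: dispersion requested but only {n} subject(s)"
                )
            sd = float(vals.std(ddof=1))
            ci = _normal_ci(float(vals.mean()), sd, n, options.confidence)
        # group breakdown: parameter-wise mean contribution across subjects
        breakdown = []
        for i, spec in enumerate(specs):
            terms = [r.breakdown[i] for r in results]
            breakdown.append(
                replace(
                    terms[0],
                    response_fraction=float(np.mean([t.response_fraction for t in terms])),
                    recovery_fraction=(
                        None
                        if terms[0].recovery_fraction is None
                        else float(np.mean([t.recovery_fraction for t in terms]))
                    ),
                    contribution=float(np.mean([t.contribution for t in terms])),
                )
            )
        groups[gid] = AdaptednessResult(
            scope="group",
            id=gid,
            value=float(vals.mean()),
            breakdown=breakdown,
            options=options,
            sd=sd,
            n=n,
            ci=ci,
        )

    pairwise: list[PairwiseTest] = []
    rng = np.random.default_rng(seed)
    gids = list(by_group)
    for i, ga in enumerate(gids):
        for gb in gids[i + 1 :]:
            va, vb = a_values[ga], a_values[gb]
            if va.size < 2 or vb.size < 2:
                continue
            if test == "welch":
                if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
                    statistic, p = (0.0, 1.0) if va.mean() == vb.mean() else (math.inf, 0.0)
                    comparison_warnings.append(
                        f"groups {ga!r} vs {gb!r}: zero within-group variance; "
                        "Welch test degenerate"
                    )
                else:
                    t_res = stats.ttest_ind(va, vb, equal_var=False)
                    statistic, p = float(t_res.statistic), float(t_res.pvalue)
            elif test == "permutation":
                statistic, p = _permutation_p(va.copy(), vb.copy(), rng, permutations)
            else:
                raise ConfigError(f"unknown test {test!r}; use 'welch' or 'permutation'")
            pairwise.append(PairwiseTest(ga, gb, statistic, p, test))

    comparison = GroupComparison(
        design="case2",
        groups=groups,
        pairwise=pairwise,
        fingerprint=options.fingerprint(specs),
        warnings=comparison_warnings,
    )
    _attach_ranks(comparison)
    return comparison


# ---------------------------------------------------------------------------
# Case III
# ---------------------------------------------------------------------------

def _cells_by_group(
    cells: Iterable[GroupCellSummary],
) -> dict[str, dict[str, dict[State, GroupCellSummary]]]:
    table: dict[str, dict[str, dict[State, GroupCellSummary]]] = {}
    for c in cells:
        slot = table.setdefault(c.group_id, {}).setdefault(c.parameter, {})
        if c.state in slot:
            raise DataError(
                f"duplicate cell ({c.group_id}, {c.parameter}, {c.state.value})"
            )
        slot[c.state] = c
    return table


def _pseudo_profiles(
    cells: Iterable[GroupCellSummary],
    specs: Sequence[ParameterSpec],
    options: IndexOptions,
) -> dict[str, SubjectProfile]:
    """One profile per group built from the cell means (mean substitution)."""
    table = _cells_by_group(cells)
    # recovery is included iff requested, or present everywhere under auto
    any_rec = any(
        State.RECOVERY in params.get(s.name, {})
        for params in table.values()
        for s in specs
    )
    use_recovery = options.include_recovery if options.include_recovery is not None else any_rec

    missing: list[str] = []
    needed = [State.PRE_LOAD, State.POST_LOAD] + ([State.RECOVERY] if use_recovery else [])
    profiles: dict[str, SubjectProfile] = {}
    for gid, params in table.items():
        values: dict[str, ParamStates] = {}
        for spec in specs:
            states = params.get(spec.name, {})
            absent = [s.value for s in needed if s not in states]
            if absent:
                missing.append(f"({gid}, {spec.name}): missing state(s) {absent}")
                continue
            values[spec.name] = ParamStates(
                pre=states[State.PRE_LOAD].mean,
                load=states[State.POST_LOAD].mean,
                rec=states[State.RECOVERY].mean if use_recovery else None,
                baseline=states[State.BASELINE].mean if State.BASELINE in states else None,
            )
        profiles[gid] = SubjectProfile(subject_id=gid, group_id=gid, values=values)
    if missing:
        raise ValidationError("missing cells: " + "; ".join(missing))
    return profiles


def _stability_for(
    stability: StabilityTable | Mapping[str, StabilityTable] | None, gid: str
) -> StabilityTable | None:
    if stability is None or isinstance(stability, StabilityTable):
        return stability
    return stability.get(gid)


def group_index_destructive(
    cells: Iterable[GroupCellSummary],
    specs: Sequence[ParameterSpec],
    stability: StabilityTable | Mapping[str, StabilityTable] | None = None,
    options: IndexOptions | None = None,
    *,
    significance_masks: Mapping[str, Mapping[str, bool]] | None = None,
    bootstrap_replicates: int | None = None,
    seed: int | None = None,
) -> GroupComparison:
    """Case III: index from per-state group means (destructive sampling).

    Each group's A is the subject index of a pseudo-profile whose state
    values are the cell means.  ``stability`` may be one shared table or a
    mapping group id -> table (per-group baseline cohorts).  When
    ``bootstrap_replicates`` is given, a parametric bootstrap — a
    beyond-the-basic-model extension — supplies an SD and percentile
    interval for each A.
    """
    options = options or IndexOptions()
    cells = list(cells)
    profiles = _pseudo_profiles(cells, specs, options)
    if significance_masks:
        profiles = {
            gid: (p.with_mask(significance_masks[gid]) if gid in significance_masks else p)
            for gid, p in profiles.items()
        }

    comparison_warnings: list[str] = []
    for gid, p in profiles.items():
        rep = validate_inputs([p], specs, options, _stability_for(stability, gid))
        rep.raise_for_errors()
        comparison_warnings.extend(rep.warnings)
    # cross-group paradoxical-direction check on the pseudo-profiles
    if not isinstance(stability, StabilityTable) and stability is not None:
        shared_stab = None
    else:
        shared_stab = stability
    cross = validate_inputs(list(profiles.values()), specs, IndexOptions(
        weighting="none",
        include_recovery=options.include_recovery,
        recovery_cap=options.recovery_cap,
    ), shared_stab)
    comparison_warnings.extend(w for w in cross.warnings if w not in comparison_warnings)

    groups: dict[str, AdaptednessResult] = {}
    for gid, p in profiles.items():
        res = subject_index(p, specs, _stability_for(stability, gid), options)
        res.scope = "group"
        res.id = gid
        ns = [c.n for c in cells if c.group_id == gid and c.n is not None]
        res.n = min(ns) if ns else None
        groups[gid] = res

    comparison = GroupComparison(
        design="case3",
        groups=groups,
        fingerprint=options.fingerprint(specs),
        warnings=comparison_warnings,
    )
    if bootstrap_replicates is not None:
        boot = bootstrap_uncertainty(
            cells,
            specs,
            stability,
            options,
            replicates=bootstrap_replicates,
            seed=seed,
            significance_masks=significance_masks,
        )
        for gid, (sd, ci) in boot.items():
            groups[gid].sd = sd
            groups[gid].ci = ci
        comparison.warnings.append(
            "Case III dispersion via parametric bootstrap (extension beyond the "
            "basic model, which leaves this SD undefined)"
        )
    _attach_ranks(comparison)
    return comparison


def bootstrap_uncertainty(
    cells: Iterable[GroupCellSummary],
    specs: Sequence[ParameterSpec],
    stability: StabilityTable | Mapping[str, StabilityTable] | None = None,
    options: IndexOptions | None = None,
    *,
    replicates: int = 1000,
    seed: int | None = None,
    significance_masks: Mapping[str, Mapping[str, bool]] | None = None,
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Parametric bootstrap for Case III group indices.

    Each cell mean is resampled from Normal(mean, sd/√n) — the sampling
    distribution of the mean — the index recomputed, and the empirical SD
    and percentile interval of A returned per group.  Deterministic under a
    fixed seed.  Resampled means are clipped at 1% of the observed mean to
    preserve positivity.
    """
    options = options or IndexOptions()
    cells = list(cells)
    if replicates < 100:
        raise ConfigError(f"replicates must be >= 100, got {replicates}")
    lacking = [
        f"({c.group_id}, {c.parameter}, {c.state.value})"
        for c in cells
        if c.sd is None or c.n is None
    ]
    if lacking:
        raise DataError("cells lacking sd/n for bootstrap: " + ", ".join(lacking))

    rng = np.random.default_rng(seed)
    base = {
        (c.group_id, c.parameter, c.state): c for c in cells
    }
    keys = sorted(base, key=lambda k: (k[0], k[1], k[2].value))
    group_ids = sorted({c.group_id for c in cells})
    draws: dict[str, list[float]] = {g: [] for g in group_ids}
    for _ in range(replicates):
        resampled = []
        for key in keys:
            c = base[key]
            se = c.sd / math.sqrt(c.n)
            value = float(rng.normal(c.mean, se))
            value = max(value, 0.01 * c.mean)
            resampled.append(replace(c, mean=value, sd=c.sd, n=c.n))
        rep_options = options if options.recovery_cap is not None else replace_cap(options)
        comp = group_index_destructive(
            resampled,
            specs,
            stability,
            rep_options,
            significance_masks=significance_masks,
        )
        for gid in group_ids:
            draws[gid].append(comp.groups[gid].value)

    lo_q = (1.0 - options.confidence) / 2.0
    out: dict[str, tuple[float, tuple[float, float]]] = {}
    for gid in group_ids:
        arr = np.asarray(draws[gid])
        sd = float(arr.std(ddof=1))
        ci = (float(np.quantile(arr, lo_q)), float(np.quantile(arr, 1 - lo_q)))
        out[gid] = (sd, ci)
    return out


def replace_cap(options: IndexOptions, cap: float = 1e6) -> IndexOptions:
    """Options copy with a large finite recovery cap, so measure-zero
    degenerate resamples cannot abort a bootstrap run."""
    return IndexOptions(
        weighting=options.weighting,
        include_recovery=options.include_recovery,
        recovery_cap=cap,
        alpha=options.alpha,
        confidence=options.confidence,
    )


# ---------------------------------------------------------------------------
# Insignificance zeroing
# ---------------------------------------------------------------------------

def _welch_from_stats(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Two-sided Welch p-value from summary statistics."""
    if m1 == m2:
        return 1.0
    if (s1 == 0 and s2 == 0) or n1 < 2 or n2 < 2:
        return 0.0 if m1 != m2 else 1.0
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    p = float(res.pvalue)
    return 0.0 if math.isnan(p) else p


def zero_insignificant(
    data: Sequence[SubjectProfile] | Sequence[GroupCellSummary],
    specs: Sequence[ParameterSpec] | None = None,
    *,
    alpha: float = 0.05,
    mask: Mapping[str, bool] | None = None,
) -> ZeroingResult:
    """Apply the rule that statistically negligible responses count as zero.

    Changes between the pre-load and post-load states that do not reach
    significance at ``alpha`` (default 0.05) — notably "paradoxical"
    direction reversals — have their response fraction taken for zero.

    With a user ``mask`` (parameter -> significant?), it is applied as
    given.  Without one, a two-sample Welch test between the F1 and F2
    values is run per group and parameter: from the subjects' raw values for
    profile data, or from (mean, sd, n) for Case III cells.  Every zeroing
    action is logged.
    """
    data = list(data)
    if not data:
        raise DataError("no data supplied")
    log: list[str] = []
    masks: dict[str, dict[str, bool]] = {}

    if isinstance(data[0], SubjectProfile):
        profiles: list[SubjectProfile] = data  # type: ignore[assignment]
        if mask is not None:
            for name, sig in mask.items():
                if not sig:
                    log.append(f"parameter {name!r}: masked insignificant (user mask)")
            masked = [p.with_mask(mask) for p in profiles]
            for p in masked:
                masks.setdefault(p.group_id, {}).update(mask)
            return ZeroingResult(masks=masks, log=log, profiles=masked)
        if specs is None:
            raise ConfigError("specs required for automatic testing on profiles")
        by_group = _group_profiles(profiles)
        masked_profiles: list[SubjectProfile] = []
        for gid, members in by_group.items():
            if len(members) < 2:
                raise DataError(
                    f"group {gid!r}: need >= 2 subjects (or a user mask) to test "
                    "significance"
                )
            gmask: dict[str, bool] = {}
            for spec in specs:
                pre = np.array([p.values[spec.name].pre for p in members])
                load = np.array([p.values[spec.name].load for p in members])
                if np.all(pre == load):
                    p_val = 1.0
                elif pre.std(ddof=1) == 0 and load.std(ddof=1) == 0:
                    p_val = 0.0
                else:
                    p_val = float(stats.ttest_ind(pre, load, equal_var=False).pvalue)
                significant = p_val <= alpha
                gmask[spec.name] = significant
                if not significant:
                    log.append(
                        f"group {gid!r}, parameter {spec.name!r}: F1 vs F2 Welch "
                        f"p = {p_val:.3f} > {alpha}; response taken for zero"
                    )
            masks[gid] = gmask
            masked_profiles.extend(p.with_mask(gmask) for p in members)
        return ZeroingResult(masks=masks, log=log, profiles=masked_profiles)

    # Case III cells
    cells: list[GroupCellSummary] = data  # type: ignore[assignment]
    table = _cells_by_group(cells)
    for gid, params in table.items():
        gmask: dict[str, bool] = {}
        for name, states in params.items():
            if State.PRE_LOAD not in states or State.POST_LOAD not in states:
                continue
            c1, c2 = states[State.PRE_LOAD], states[State.POST_LOAD]
            if c1.sd is None or c1.n is None or c2.sd is None or c2.n is None:
                raise DataError(
                    f"cell ({gid}, {name}): sd/n required for automatic "
                    "significance testing"
                )
            p_val = _welch_from_stats(c1.mean, c1.sd, c1.n, c2.mean, c2.sd, c2.n)
            significant = p_val <= alpha
            gmask[name] = significant
            if not significant:
                log.append(
                    f"group {gid!r}, parameter {name!r}: F1 vs F2 Welch "
                    f"p = {p_val:.3f} > {alpha}; response taken for zero"
                )
        masks[gid] = gmask
    return ZeroingResult(masks=masks, log=log)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_groups(
    results: Mapping[str, float] | Mapping[str, AdaptednessResult],
) -> dict[str, int]:
    """Dense descending ranks: rank 1 is the largest (most adaptive) A.

    Tied groups share a rank (input order breaks display ties) and trigger a
    :class:`~adaptindex.errors.RankTieWarning`.  When full results are
    passed, their option fingerprints must agree.
    """
    if not results:
        raise DataError("no groups to rank")
    values: dict[str, float] = {}
    fingerprints = set()
    for gid, res in results.items():
        if isinstance(res, AdaptednessResult):
            values[gid] = res.value
            fingerprints.add(res.options.fingerprint([]))
        else:
            values[gid] = float(res)
    if len(fingerprints) > 1:
        raise ValidationError(
            "groups computed under different option fingerprints cannot be ranked together"
        )
    distinct = sorted(set(values.values()), reverse=True)
    if len(distinct) < len(values):
        warnings.warn(
            "tied adaptedness values; dense ranking with input-order tie-break",
            RankTieWarning,
            stacklevel=2,
        )
    rank_of = {v: i + 1 for i, v in enumerate(distinct)}
    return {gid: rank_of[v] for gid, v in values.items()}


def _attach_ranks(comparison: GroupComparison) -> None:
    for gid, rank in rank_groups(comparison.values).items():
        comparison.groups[gid].rank = rank
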