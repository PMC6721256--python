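"""Tabular data and configuration I/O, plus the bundled example studies.

Measurement files are delimiter-separated text (comma or tab, auto-detected)
with a mandatory header.  Two schemas are supported:

* long format (Case I/II): ``subject_id, group_id, parameter, state, value``
  — one row per measurement;
* summary format (Case III): ``group_id, parameter, state, mean, sd, n`` —
  one row per destructively sampled cell.

State labels accept ``F0/F1/F2/F3`` or ``baseline/pre/load/recovery``.

Analysis configuration is a human-editable YAML file declaring each
parameter's category (the one scientific judgement the package never makes
for you), optional fixed stability coefficients, the weighting mode, and
design options.

Two published worked examples ship as fixtures: ``example1_rats`` (swimming
rats under training and adaptogen pre-treatment; destructive sampling, no
recovery state) and ``example2_horses`` (race horses before/after an ~80%
maximal run with a 1 h recovery state).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .core import (
    AdaptednessResult,
    Category,
    IndexOptions,
    ParameterSpec,
    ParamStates,
    StabilityEntry,
    StabilityTable,
    State,
    SubjectProfile,
    TermBreakdown,
)
from .designs import GroupCellSummary, GroupComparison, PairwiseTest
from .errors import ConfigError, DataError

__all__ = [
    "StudyConfig",
    "Fixture",
    "read_measurements",
    "load_fixture",
    "write_report",
    "read_report",
]

LONG_COLUMNS = ["subject_id", "group_id", "parameter", "state", "value"]
SUMMARY_COLUMNS = ["group_id", "parameter", "state", "mean", "sd", "n"]
FIXTURE_NAMES = ("example1_rats", "example2_horses")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Declarative description of one analysis.

    ``stability_source`` declares where S coefficients come from:
    ``{"policy": "supplied"}`` uses the per-parameter ``stability`` values
    from the config; ``{"policy": "reference_group", "group": G, "state": S}``
    computes them from one designated baseline cohort;
    ``{"policy": "per_group", "state": S}`` computes one table per group;
    ``{"policy": "mean_of_groups", "state": S}`` averages the per-group S
    values into one shared table.
    """

    design: str = "case1"
    weighting: str = "stability"
    include_recovery: bool | None = None
    alpha: float = 0.05
    confidence: float = 0.95
    parameters: list[dict] = field(default_factory=list)
    stability_source: dict = field(default_factory=lambda: {"policy": "supplied"})
    recovery_cap: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in ("case1", "case2", "case3"):
            raise ConfigError(f"design must be case1/case2/case3, got {self.design!r}")
        if self.weighting not in ("stability", "none"):
            raise ConfigError(f"weighting must be 'stability' or 'none', got {self.weighting!r}")
        if not self.parameters:
            raise ConfigError("config declares no parameters")
        for p in self.parameters:
            if "name" not in p or "category" not in p:
                raise ConfigError(f"parameter entry missing name/category: {p}")
            Category.parse(p["category"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        known = {
            "design", "weighting", "include_recovery", "alpha", "confidence",
            "parameters", "stability_source", "recovery_cap", "metadata",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "design": self.design,
            "weighting": self.weighting,
            "include_recovery": self.include_recovery,
            "alpha": self.alpha,
            "confidence": self.confidence,
            "parameters": self.parameters,
            "stability_source": self.stability_source,
            "recovery_cap": self.recovery_cap,
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)

    @property
    def specs(self) -> list[ParameterSpec]:
        return [
            ParameterSpec(p["name"], Category.parse(p["category"]), p.get("units", ""))
            for p in self.parameters
        ]

    @property
    def options(self) -> IndexOptions:
        return IndexOptions(
            weighting=self.weighting,
            include_recovery=self.include_recovery,
            recovery_cap=self.recovery_cap,
            alpha=self.alpha,
            confidence=self.confidence,
        )

    def check_parameters(self, names: Sequence[str]) -> None:
        declared = {p["name"] for p in self.parameters}
        missing = sorted(set(names) - declared)
        if missing:
            raise ConfigError(
                f"data references parameters absent from the config: {missing}"
            )

    # -- stability resolution ------------------------------------------------

    def stability_tables(
        self, cells: Sequence[GroupCellSummary] | None = None
    ) -> StabilityTable | dict[str, StabilityTable] | None:
        """Resolve S per the configured policy.

        Returns one shared table, or a mapping group id -> table when the
        supplied values (or the policy) are group-specific.  ``cells`` are
        required for the computed policies.
        """
        policy = self.stability_source.get("policy", "supplied")
        if policy == "supplied":
            return self._supplied_tables()
        state = State.parse(self.stability_source.get("state", "F0"))
        if cells is None:
            raise ConfigError(f"stability policy {policy!r} needs baseline data")
        summaries: dict[str, dict[str, tuple[float, float]]] = {}
        for c in cells:
            if c.state is state:
                if c.sd is None:
                    raise DataError(
                        f"cell ({c.group_id}, {c.parameter}): sd required to compute S"
                    )
                summaries.setdefault(c.group_id, {})[c.parameter] = (c.mean, c.sd)
        if not summaries:
            raise DataError(f"no baseline rows at state {state.value} to compute S from")
        if policy == "reference_group":
            gid = str(self.stability_source.get("group"))
            if gid not in summaries:
                raise DataError(f"reference group {gid!r} has no {state.value} rows")
            return StabilityTable.from_summaries(
                summaries[gid], source=f"group {gid} at {state.value}"
            )
        if policy == "per_group":
            return {
                gid: StabilityTable.from_summaries(s, source=f"group {gid} at {state.value}")
                for gid, s in summaries.items()
            }
        if policy == "mean_of_groups":
            names = {n for s in summaries.values() for n in s}
            entries = {}
            for n in names:
                vals = [
                    StabilityTable.from_summaries({n: s[n]}, source="tmp")[n].S
                    for s in summaries.values()
                    if n in s
                ]
                entries[n] = StabilityEntry(
                    sum(vals) / len(vals),
                    provenance="computed",
                    source=f"mean of {len(vals)} group baselines at {state.value}",
                )
            return StabilityTable(entries)
        raise ConfigError(f"unknown stability policy {policy!r}")

    def _supplied_tables(self) -> StabilityTable | dict[str, StabilityTable] | None:
        scalar: dict[str, StabilityEntry] = {}
        per_group: dict[str, dict[str, StabilityEntry]] = {}
        for p in self.parameters:
            s = p.get("stability")
            if s is None:
                continue
            if isinstance(s, Mapping):
                for gid, value in s.items():
                    per_group.setdefault(str(gid), {})[p["name"]] = StabilityEntry(
                        float(value), provenance="supplied"
                    )
            else:
                scalar[p["name"]] = StabilityEntry(float(s), provenance="supplied")
        if per_group:
            if scalar:  # shared values apply to every group
                for entries in per_group.values():
                    for name, e in scalar.items():
                        entries.setdefault(name, e)
            return {gid: StabilityTable(entries) for gid, entries in per_group.items()}
        if scalar:
            return StabilityTable(scalar)
        return None


# ---------------------------------------------------------------------------
# Measurement files
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"data file not found: {path}")
    if not path.read_text(encoding="utf-8").strip():
        raise DataError(f"data file {path} is empty")
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise DataError(f"data file {path} is empty") from None
    except csv.Error as exc:
        raise DataError(f"data file {path}: {exc}") from None
    if df.empty:
        raise DataError(f"data file {path} has a header but no rows")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    parsed = pd.to_numeric(df[column].str.strip(), errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based with header
        raise DataError(
            f"{path}, row {row}: non-numeric {column} value {df[column][bad.idxmax()]!r}"
        )
    if parsed.isna().any():
        row = int(parsed.isna().idxmax()) + 2
        raise DataError(f"{path}, row {row}: missing {column} value")
    return parsed


def _parse_states(df: pd.DataFrame, path: Path) -> list[State]:
    out = []
    for idx, raw in df["state"].items():
        try:
            out.append(State.parse(raw))
        except DataError as exc:
            raise DataError(f"{path}, row {int(idx) + 2}: {exc}") from None
    return out


def read_measurements(
    path: str | Path, design: str
) -> list[SubjectProfile] | list[GroupCellSummary]:
    """Read a measurement file for the given design.

    ``design`` ``"case1"``/``"case2"`` expects the long format and returns
    :class:`~adaptindex.core.SubjectProfile` objects; ``"case3"`` expects the
    summary format and returns :class:`~adaptindex.designs.GroupCellSummary`
    objects.  Duplicate keys, unknown state labels, non-numeric values and
    empty files are rejected with the offending row number.
    """
    path = Path(path)
    df = _read_table(path)
    if design in ("case1", "case2"):
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"{path}: missing columns {missing} for long format")
        df["__state"] = _parse_states(df, path)
        values = _numeric(df, "value", path)
        seen: dict[tuple, int] = {}
        profiles: dict[tuple[str, str], dict[str, dict[State, float]]] = {}
        for idx, row in df.iterrows():
            key = (row["subject_id"], row["parameter"], row["__state"])
            if key in seen:
                raise DataError(
                    f"{path}, row {int(idx) + 2}: duplicate (subject, parameter, "
                    f"state) = ({key[0]}, {key[1]}, {key[2].value}); first seen at "
                    f"row {seen[key]}"
                )
            seen[key] = int(idx) + 2
            profiles.setdefault((row["subject_id"], row["group_id"]), {}).setdefault(
                row["parameter"], {}
            )[row["__state"]] = float(values[idx])
        out: list[SubjectProfile] = []
        for (sid, gid), params in profiles.items():
            vals: dict[str, ParamStates] = {}
            for name, states in params.items():
                if State.PRE_LOAD not in states or State.POST_LOAD not in states:
                    raise DataError(
                        f"{path}: subject {sid!r}, parameter {name!r}: both F1 "
                        "(pre) and F2 (load) states are required"
                    )
                vals[name] = ParamStates(
                    pre=states[State.PRE_LOAD],
                    load=states[State.POST_LOAD],
                    rec=states.get(State.RECOVERY),
                    baseline=states.get(State.BASELINE),
                )
            out.append(SubjectProfile(subject_id=sid, group_id=gid, values=vals))
        return out

    if design == "case3":
        missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"{path}: missing columns {missing} for summary format")
        df["__state"] = _parse_states(df, path)
        means = _numeric(df, "mean", path)
        sds = _numeric(df, "sd", path)
        ns = _numeric(df, "n", path)
        seen = {}
        cells: list[GroupCellSummary] = []
        for idx, row in df.iterrows():
            key = (row["group_id"], row["parameter"], row["__state"])
            if key in seen:
                raise DataError(
                    f"{path}, row {int(idx) + 2}: duplicate (group, parameter, "
                    f"state) = ({key[0]}, {key[1]}, {key[2].value}); first seen "
                    f"at row {seen[key]}"
                )
            seen[key] = int(idx) + 2
            cells.append(
                GroupCellSummary(
                    group_id=row["group_id"],
                    parameter=row["parameter"],
                    state=row["__state"],
                    mean=float(means[idx]),
                    sd=float(sds[idx]),
                    n=int(ns[idx]),
                )
            )
        return cells

    raise ConfigError(f"design must be case1/case2/case3, got {design!r}")


def write_measurements(
    data: Sequence[SubjectProfile] | Sequence[GroupCellSummary], path: str | Path
) -> None:
    """Write profiles (long format) or cells (summary format) back to CSV."""
    rows: list[dict] = []
    if data and isinstance(data[0], SubjectProfile):
        for p in data:  # type: ignore[union-attr]
            for name, ps in p.values.items():
                pairs = [(State.PRE_LOAD, ps.pre), (State.POST_LOAD, ps.load)]
                if ps.rec is not None:
                    pairs.append((State.RECOVERY, ps.rec))
                if ps.baseline is not None:
                    pairs.append((State.BASELINE, ps.baseline))
                for state, value in pairs:
                    rows.append(
                        {
                            "subject_id": p.subject_id,
                            "group_id": p.group_id,
                            "parameter": name,
                            "state": state.value,
                            "value": repr(value),
                        }
                    )
        columns = LONG_COLUMNS
    else:
        for c in data:  # type: ignore[assignment]
            rows.append(
                {
                    "group_id": c.group_id,
                    "parameter": c.parameter,
                    "state": c.state.value,
                    "mean": repr(c.mean),
                    "sd": "" if c.sd is None else repr(c.sd),
                    "n": "" if c.n is None else c.n,
                }
            )
        columns = SUMMARY_COLUMNS
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A bundled worked example: data, configuration and the published
    per-term values and totals it is checked against."""

    name: str
    cells: list[GroupCellSummary]
    config: StudyConfig
    printed: dict


def load_fixture(name: str) -> Fixture:
    """Load a bundled example study (``example1_rats`` or ``example2_horses``)."""
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    root = resources.files("adaptindex").joinpath("data", name)
    with resources.as_file(root) as base:
        cells = read_measurements(base / "data.csv", "case3")
        config = StudyConfig.from_yaml(base / "config.yaml")
        with open(base / "printed.yaml", encoding="utf-8") as fh:
            printed = yaml.safe_load(fh)
    return Fixture(name=name, cells=cells, config=config, printed=printed)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _term_to_dict(t: TermBreakdown) -> dict:
    return {
        "parameter": t.parameter,
        "category": t.category.value,
        "S": t.S,
        "response_fraction": t.response_fraction,
        "recovery_fraction": t.recovery_fraction,
        "weighting": t.weighting,
        "contribution": t.contribution,
        "zeroed_insignificant": t.zeroed_insignificant,
    }


def _term_from_dict(d: dict) -> TermBreakdown:
    return TermBreakdown(
        parameter=d["parameter"],
        category=Category.parse(d["category"]),
        S=d["S"],
        response_fraction=d["response_fraction"],
        recovery_fraction=d["recovery_fraction"],
        weighting=d["weighting"],
        contribution=d["contribution"],
        zeroed_insignificant=d["zeroed_insignificant"],
    )


def _options_to_dict(o: IndexOptions) -> dict:
    return {
        "weighting": o.weighting,
        "include_recovery": o.include_recovery,
        "recovery_cap": o.recovery_cap,
        "alpha": o.alpha,
        "confidence": o.confidence,
    }


def comparison_to_dict(comparison: GroupComparison) -> dict:
    """Lossless JSON-ready representation of a group comparison."""
    return {
        "design": comparison.design,
        "fingerprint": comparison.fingerprint,
        "warnings": comparison.warnings,
        "groups": {
            gid: {
                "scope": r.scope,
                "value": r.value,
                "sd": r.sd,
                "n": r.n,
                "ci": list(r.ci) if r.ci else None,
                "rank": r.rank,
                "options": _options_to_dict(r.options),
                "breakdown": [_term_to_dict(t) for t in r.breakdown],
            }
            for gid, r in comparison.groups.items()
        },
        "pairwise": [
            {
                "group_a": t.group_a,
                "group_b": t.group_b,
                "statistic": t.statistic,
                "p_value": t.p_value,
                "method": t.method,
            }
            for t in comparison.pairwise
        ],
    }


def comparison_from_dict(data: dict) -> GroupComparison:
    def _tuplify(obj: Any) -> Any:
        return tuple(_tuplify(x) for x in obj) if isinstance(obj, list) else obj

    groups = {}
    for gid, g in data["groups"].items():
        groups[gid] = AdaptednessResult(
            scope=g["scope"],
            id=gid,
            value=g["value"],
            breakdown=[_term_from_dict(t) for t in g["breakdown"]],
            options=IndexOptions(**g["options"]),
            sd=g["sd"],
            n=g["n"],
            ci=tuple(g["ci"]) if g["ci"] else None,
            rank=g["rank"],
        )
    return GroupComparison(
        design=data["design"],
        groups=groups,
        pairwise=[PairwiseTest(**t) for t in data["pairwise"]],
        fingerprint=_tuplify(data["fingerprint"]),
        warnings=list(data["warnings"]),
    )


def write_report(
    comparison: GroupComparison, path: str | Path, format: str = "tsv"
) -> None:
    """Write a deterministic report.

    ``tsv`` mirrors the published layout — one row per parameter, one column
    per group, final A and adaptive-rank rows, 3-decimal rendering — with
    the options fingerprint and warnings as leading comment lines.  ``json``
    is the machine-readable twin and round-trips losslessly at full
    precision via :func:`read_report`.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(comparison_to_dict(comparison), fh, indent=2)
            fh.write("\n")
        return
    if format != "tsv":
        raise ConfigError(f"unknown report format {format!r}; use 'tsv' or 'json'")

    lines = [f"# design: {comparison.design}", f"# options: {comparison.fingerprint}"]
    for w in comparison.warnings:
        lines.append(f"# warning: {w}")
    gids = list(comparison.groups)
    lines.append("\t".join(["parameter"] + gids))
    if gids:
        n_terms = len(comparison.groups[gids[0]].breakdown)
        for i in range(n_terms):
            name = comparison.groups[gids[0]].breakdown[i].parameter
            row = [name] + [
                f"{comparison.groups[g].breakdown[i].contribution:+.3f}" for g in gids
            ]
            lines.append("\t".join(row))
        lines.append("\t".join(["A"] + [f"{comparison.groups[g].value:+.3f}" for g in gids]))
        lines.append(
            "\t".join(
                ["adaptive_rank"]
                + [str(comparison.groups[g].rank) if comparison.groups[g].rank else "" for g in gids]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_report(path: str | Path) -> GroupComparison:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        return comparison_from_dict(json.load(fh))
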