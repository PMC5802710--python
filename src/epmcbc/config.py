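"""Analysis configuration: behavioral measures and profiling parameters.

The cutoff-behavioral-criteria (CBC) procedure is parameterised by a set of
m behavioral measures (each with a declared "deviant" tail), a percentile
level q applied to the control distribution, and a criterion k: an animal
is classified affected when at least k of its m measures fall in the
deviant tail of the control population.

The default configuration carries seven elevated-plus-maze (EPM) measures
built from per-zone distance and duration summaries. The concrete
seven-measure set used in published CBC analyses of the EPM is rarely
enumerated in full; the set shipped here (open/closed arm distance and
duration, total distance, and the two open/closed anxiety indices) is a
documented stand-in with the conventional tail directions: low open-arm
activity, low overall activity and low open/closed ratios indicate high
anxiety, while high closed-arm duration does.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError

__all__ = [
    "Direction",
    "MeasureSpec",
    "ProfilingConfig",
    "AnovaPlan",
    "DEFAULT_MEASURES",
    "DEFAULT_GROUPS",
    "DEFAULT_GROUP_FACTORS",
    "DEFAULT_ANOVA_RESPONSES",
    "default_config",
    "default_anova_plan",
    "load_config",
    "save_config",
]


class Direction(str, enum.Enum):
    """Which tail of the control distribution counts as deviant."""

    FLAG_LOW = "flag-low"
    FLAG_HIGH = "flag-high"

    @classmethod
    def parse(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, Direction):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ConfigError(
                f"direction must be 'flag-low' or 'flag-high', got {value!r}"
            ) from None


@dataclass(frozen=True)
class MeasureSpec:
    """One behavioral measure: name, units and its deviant tail."""

    name: str
    units: str
    direction: Direction

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ConfigError("measure name must be a non-empty string")
        object.__setattr__(self, "direction", Direction.parse(self.direction))


#: The seven default EPM profiling measures (a documented stand-in set).
DEFAULT_MEASURES: tuple[MeasureSpec, ...] = (
    MeasureSpec("open_arm_distance", "cm", Direction.FLAG_LOW),
    MeasureSpec("open_arm_duration", "s", Direction.FLAG_LOW),
    MeasureSpec("closed_arm_distance", "cm", Direction.FLAG_LOW),
    MeasureSpec("closed_arm_duration", "s", Direction.FLAG_HIGH),
    MeasureSpec("total_distance", "cm", Direction.FLAG_LOW),
    MeasureSpec("distance_anxiety_index", "ratio", Direction.FLAG_LOW),
    MeasureSpec("duration_anxiety_index", "ratio", Direction.FLAG_LOW),
)

#: Standard six-group juvenile-stress x fluoxetine design.
DEFAULT_GROUPS: tuple[str, ...] = (
    "control",
    "control+FLXjuv",
    "control+FLXadlt",
    "JVS",
    "JVS+FLXjuv",
    "JVS+FLXadlt",
)

#: Group label -> (stress level, drug level) for the two-way ANOVA.
DEFAULT_GROUP_FACTORS: Mapping[str, tuple[str, str]] = {
    "control": ("control", "noFLX"),
    "control+FLXjuv": ("control", "FLXjuv"),
    "control+FLXadlt": ("control", "FLXadlt"),
    "JVS": ("JVS", "noFLX"),
    "JVS+FLXjuv": ("JVS", "FLXjuv"),
    "JVS+FLXadlt": ("JVS", "FLXadlt"),
}

#: Responses analysed by the averaged-group ANOVA stage.
DEFAULT_ANOVA_RESPONSES: tuple[str, ...] = (
    "total_distance",
    "distance_anxiety_index",
    "duration_anxiety_index",
)


@dataclass(frozen=True)
class ProfilingConfig:
    """Full parameterisation of the CBC classification.

    Parameters
    ----------
    measures
        Ordered measure set (length m).
    q
        Percentile level in (0, 1) applied to the control distribution
        (0.20 flags the lower/upper 20%).
    criterion_k
        Minimum number of deviant measures for an "affected" call.
    control_group
        Group label providing the reference (normal) population.
    groups
        All group labels expected in the data. Empty tuple = accept any.
    reference_proportion
        Affected fraction of the goodness-of-fit reference split
        (0.20 -> the 20:80 control norm).
    min_control_n
        Smallest control group from which cutoffs may be derived.
    strict_comparison
        If True, use strict inequalities at the cutoffs instead of the
        default inclusive ones.
    """

    measures: tuple[MeasureSpec, ...] = DEFAULT_MEASURES
    q: float = 0.20
    criterion_k: int = 4
    control_group: str = "control"
    groups: tuple[str, ...] = DEFAULT_GROUPS
    reference_proportion: float = 0.20
    min_control_n: int = 10
    strict_comparison: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "measures", tuple(self.measures))
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [m.name for m in self.measures]
        if not names:
            raise ConfigError("at least one measure must be configured")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate measure name(s): {', '.join(dupes)}")
        if not 0.0 < self.q < 1.0:
            raise ConfigError(f"percentile level q must be in (0, 1), got {self.q}")
        if not 1 <= self.criterion_k <= len(names):
            raise ConfigError(
                f"criterion_k must satisfy 1 <= k <= m={len(names)}, "
                f"got {self.criterion_k}"
            )
        if not 0.0 < self.reference_proportion < 1.0:
            raise ConfigError("reference_proportion must be in (0, 1)")
        if self.min_control_n < 1:
            raise ConfigError("min_control_n must be >= 1")
        if self.groups and self.control_group not in self.groups:
            raise ConfigError(
                f"control_group {self.control_group!r} is not in the group list"
            )

    @property
    def measure_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.measures)

    @property
    def n_measures(self) -> int:
        return len(self.measures)

    def with_(self, **changes) -> "ProfilingConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class AnovaPlan:
    """Averaged-group analysis plan: which responses to analyse and how
    group labels decompose into the two design factors."""

    responses: tuple[str, ...] = DEFAULT_ANOVA_RESPONSES
    factor_names: tuple[str, str] = ("stress", "drug")
    group_factors: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_FACTORS)
    )
    posthoc_factor: str = "drug"
    ss_type: int = 3

    def __post_init__(self) -> None:
        if self.ss_type not in (1, 2, 3):
            raise ConfigError("ss_type must be 1, 2 or 3")
        if self.posthoc_factor not in self.factor_names:
            raise ConfigError(
                f"posthoc_factor {self.posthoc_factor!r} is not one of "
                f"{self.factor_names}"
            )


def default_config() -> ProfilingConfig:
    """The stock seven-measure, q=0.20, k=4 EPM configuration."""
    return ProfilingConfig()


def default_anova_plan() -> AnovaPlan:
    return AnovaPlan()


def _measures_from_items(items: Iterable[Mapping]) -> tuple[MeasureSpec, ...]:
    specs = []
    for item in items:
        try:
            specs.append(
                MeasureSpec(item["name"], item.get("units", ""), item["direction"])
            )
        except KeyError as exc:
            raise ConfigError(f"measure entry missing key {exc}") from None
    return tuple(specs)


def load_config(path) -> tuple[ProfilingConfig, AnovaPlan]:
    """Read a YAML configuration file.

    Recognised top-level keys: ``measures`` (list of name/units/direction
    mappings), ``q``, ``criterion_k``, ``control_group``, ``groups``,
    ``reference_proportion``, ``min_control_n``, ``strict_comparison``,
    and an optional ``anova`` section (``responses``, ``factor_names``,
    ``group_factors``, ``posthoc_factor``, ``ss_type``). Omitted keys
    fall back to the defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    kwargs = {}
    if "measures" in raw:
        kwargs["measures"] = _measures_from_items(raw["measures"])
    for key in (
        "q",
        "criterion_k",
        "control_group",
        "reference_proportion",
        "min_control_n",
        "strict_comparison",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "groups" in raw:
        kwargs["groups"] = tuple(raw["groups"])
    config = ProfilingConfig(**kwargs)

    anova_raw = raw.get("anova", {})
    akwargs = {}
    if "responses" in anova_raw:
        akwargs["responses"] = tuple(anova_raw["responses"])
    if "factor_names" in anova_raw:
        akwargs["factor_names"] = tuple(anova_raw["factor_names"])
    if "group_factors" in anova_raw:
        akwargs["group_factors"] = {
            g: tuple(v) for g, v in anova_raw["group_factors"].items()
        }
    for key in ("posthoc_factor", "ss_type"):
        if key in anova_raw:
            akwargs[key] = anova_raw[key]
    plan = AnovaPlan(**akwargs)
    return config, plan


def save_config(config: ProfilingConfig, plan: AnovaPlan, path) -> None:
    """Write a configuration (re-loadable by :func:`load_config`)."""
    doc = {
        "measures": [
            {"name": m.name, "units": m.units, "direction": m.direction.value}
            for m in config.measures
        ],
        "q": config.q,
        "criterion_k": config.criterion_k,
        "control_group": config.control_group,
        "groups": list(config.groups),
        "reference_proportion": config.reference_proportion,
        "min_control_n": config.min_control_n,
        "strict_comparison": config.strict_comparison,
        "anova": {
            "responses": list(plan.responses),
            "factor_names": list(plan.factor_names),
            "group_factors": {g: list(v) for g, v in plan.group_factors.items()},
            "posthoc_factor": plan.posthoc_factor,
            "ss_type": plan.ss_type,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
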