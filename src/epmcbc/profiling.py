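"""Cutoff-behavioral-criteria (CBC) classification.

The CBC procedure treats the control group as the normal population:
for each behavioral measure the empirical q-th percentile (nearest-rank,
lower tail for ``flag-low`` measures, upper tail for ``flag-high``) is
taken as a cutoff, every animal's value is compared against it, and an
animal is classified "affected" when at least k of its m measures fall
in the deviant tail.

Numerical conventions
---------------------
* Percentile estimator: nearest rank, i.e. the order statistic at rank
  ceil(q*n). With no ties, exactly ceil(q*n) of n control values are
  flagged, and flags are invariant under any strictly increasing
  transform of a measure.
* Tie handling: comparisons are inclusive by default (<= for flag-low,
  >= for flag-high), so the control animal that defines a cutoff is
  itself flagged. A strict mode is available via the configuration.
* A measure that is constant across the control group is kept (dropping
  it would silently change the k-of-m criterion) but a warning is
  attached to the cutoff set: under the inclusive rule such a measure
  flags every animal tying the constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Direction, ProfilingConfig
from .errors import ConfigError, CutoffWarning, ValidationError
from .io import BehaviorTable

__all__ = [
    "Cutoff",
    "CutoffSet",
    "AnimalProfile",
    "GroupDistribution",
    "nearest_rank",
    "compute_cutoffs",
    "flag_animal",
    "classify",
    "profile_groups",
    "profiles_to_frame",
    "null_classification_rate",
]


@dataclass(frozen=True)
class Cutoff:
    """Per-measure cutoff: value in the measure's units plus tail."""

    measure: str
    value: float
    direction: Direction


@dataclass(frozen=True)
class CutoffSet:
    """Control-derived cutoffs for a full measure set.

    Attributes
    ----------
    cutoffs
        One :class:`Cutoff` per configured measure, in measure order.
    q
        Percentile level the cutoffs were taken at.
    control_n
        Size of the control population that produced them.
    inclusive
        Whether flagging comparisons include the cutoff value.
    warnings
        Human-readable notes (e.g. constant control measures).
    """

    cutoffs: tuple[Cutoff, ...]
    q: float
    control_n: int
    inclusive: bool = True
    warnings: tuple[str, ...] = ()

    def __getitem__(self, measure: str) -> Cutoff:
        for c in self.cutoffs:
            if c.measure == measure:
                return c
        raise ConfigError(f"no cutoff for measure {measure!r}")

    def __iter__(self) -> Iterator[Cutoff]:
        return iter(self.cutoffs)

    @property
    def measure_names(self) -> tuple[str, ...]:
        return tuple(c.measure for c in self.cutoffs)


@dataclass(frozen=True)
class AnimalProfile:
    """Per-animal classification record."""

    animal_id: str
    group: str
    flags: tuple[bool, ...]
    deviation_count: int
    affected: bool


@dataclass(frozen=True)
class GroupDistribution:
    """A group's affected/unaffected split."""

    group: str
    n: int
    n_affected: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_affected <= self.n:
            raise ValidationError(
                f"group {self.group!r}: n_affected={self.n_affected} "
                f"outside [0, {self.n}]"
            )

    @property
    def n_unaffected(self) -> int:
        return self.n - self.n_affected

    @property
    def proportion_affected(self) -> float:
        return self.n_affected / self.n if self.n else float("nan")


def nearest_rank(values: Sequence[float], q: float, direction: Direction) -> float:
    """Nearest-rank empirical percentile of ``values`` at level ``q``.

    For ``flag-low`` this is the order statistic at rank ceil(q*n); for
    ``flag-high`` it is the mirrored order statistic at rank
    n - ceil(q*n) + 1 (i.e. the upper-tail cutoff at level 1-q).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValidationError("cannot take a percentile of an empty sample")
    # guard against binary representation of decimal q (e.g. 0.2*35)
    rank = math.ceil(round(q * n, 10))
    rank = min(max(rank, 1), n)
    if Direction.parse(direction) is Direction.FLAG_LOW:
        return float(v[rank - 1])
    return float(v[n - rank])


def compute_cutoffs(control: BehaviorTable, config: ProfilingConfig) -> CutoffSet:
    """Derive the per-measure cutoff set from the control population.

    ``control`` must contain only rows of ``config.control_group`` and
    at least ``config.min_control_n`` animals. Constant control measures
    trigger a :class:`CutoffWarning` and a note on the returned set.
    """
    groups = set(control.group_labels)
    if groups - {config.control_group}:
        raise ValidationError(
            f"control table contains non-control group(s): "
            f"{sorted(groups - {config.control_group})}"
        )
    n = len(control)
    if n < config.min_control_n:
        raise ValidationError(
            f"control group has {n} animals; at least "
            f"{config.min_control_n} are required to derive percentile cutoffs"
        )
    cutoffs = []
    notes = []
    for spec in config.measures:
        vals = control.values(spec.name)
        if np.min(vals) == np.max(vals):
            msg = (
                f"measure {spec.name!r} is constant across the control group; "
                f"inclusive flagging will flag every animal tying the constant"
            )
            warnings.warn(msg, CutoffWarning, stacklevel=2)
            notes.append(msg)
        cutoffs.append(
            Cutoff(spec.name, nearest_rank(vals, config.q, spec.direction),
                   spec.direction)
        )
    return CutoffSet(
        cutoffs=tuple(cutoffs),
        q=config.q,
        control_n=n,
        inclusive=not config.strict_comparison,
        warnings=tuple(notes),
    )


def flag_animal(row: Mapping[str, float], cutoffs: CutoffSet) -> tuple[bool, ...]:
    """Compare one animal's measures against the cutoff set.

    Returns one boolean per measure in cutoff order; True marks a value
    in the deviant tail.
    """
    flags = []
    for c in cutoffs:
        if c.measure not in row:
            raise ConfigError(f"row is missing configured measure {c.measure!r}")
        v = float(row[c.measure])
        if c.direction is Direction.FLAG_LOW:
            hit = v <= c.value if cutoffs.inclusive else v < c.value
        else:
            hit = v >= c.value if cutoffs.inclusive else v > c.value
        flags.append(bool(hit))
    return tuple(flags)


def classify(flags: Sequence[bool], config: ProfilingConfig) -> tuple[int, bool]:
    """Apply the k-of-m criterion to a flag vector.

    Returns ``(deviation_count, affected)`` with
    ``affected = deviation_count >= criterion_k``.
    """
    if len(flags) != config.n_measures:
        raise ConfigError(
            f"expected {config.n_measures} flags, got {len(flags)}"
        )
    count = int(sum(bool(f) for f in flags))
    return count, count >= config.criterion_k


def profile_groups(
    table: BehaviorTable,
    cutoffs: CutoffSet,
    config: ProfilingConfig,
) -> tuple[list[GroupDistribution], list[AnimalProfile]]:
    """Classify every animal and tally affected counts per group.

    Every group label present in ``table`` must appear in
    ``config.groups`` (when that list is non-empty); configured groups
    absent from the table yield an (n=0, n_affected=0) distribution.
    The control group is profiled against its own cutoffs exactly like
    every other group.
    """
    if config.groups:
        unknown = set(table.group_labels) - set(config.groups)
        if unknown:
            raise ValidationError(
                f"unknown group label(s): {', '.join(sorted(unknown))}"
            )
        group_order = list(config.groups)
    else:
        group_order = list(table.group_labels)

    # vectorised equivalent of flag_animal/classify applied row by row
    df = table.frame
    flag_cols = np.empty((len(df), len(cutoffs.cutoffs)), dtype=bool)
    for j, c in enumerate(cutoffs.cutoffs):
        v = df[c.measure].to_numpy()
        if c.direction is Direction.FLAG_LOW:
            flag_cols[:, j] = v <= c.value if cutoffs.inclusive else v < c.value
        else:
            flag_cols[:, j] = v >= c.value if cutoffs.inclusive else v > c.value
    counts = flag_cols.sum(axis=1)
    affected_arr = counts >= config.criterion_k

    profiles: list[AnimalProfile] = []
    tallies = {g: [0, 0] for g in group_order}  # [n, n_affected]
    for i, (animal_id, group) in enumerate(zip(df["animal_id"], df["group"])):
        profiles.append(
            AnimalProfile(
                animal_id,
                group,
                tuple(bool(f) for f in flag_cols[i]),
                int(counts[i]),
                bool(affected_arr[i]),
            )
        )
        tallies[group][0] += 1
        tallies[group][1] += int(affected_arr[i])
    distributions = [
        GroupDistribution(g, *tallies[g]) for g in group_order
    ]
    return distributions, profiles


def profiles_to_frame(
    profiles: Sequence[AnimalProfile], cutoffs: CutoffSet
) -> pd.DataFrame:
    """Per-animal profile table: one 0/1 column per measure flag plus
    deviation count and affected call (the profile CSV layout)."""
    names = cutoffs.measure_names
    rows = []
    for p in profiles:
        rec = {"animal_id": p.animal_id, "group": p.group}
        rec.update({f"flag_{m}": int(f) for m, f in zip(names, p.flags)})
        rec["deviation_count"] = p.deviation_count
        rec["affected"] = int(p.affected)
        rows.append(rec)
    cols = ["animal_id", "group", *(f"flag_{m}" for m in names),
            "deviation_count", "affected"]
    return pd.DataFrame(rows, columns=cols)


def null_classification_rate(m: int, k: int, per_measure_rate: float) -> float:
    """Probability that >= k of m independent measures are flagged when
    each flags with the given per-measure probability.

    This is the classifier's false-positive rate for a normal animal
    under measure independence: the binomial upper tail
    sum_{j=k..m} C(m, j) p^j (1-p)^(m-j). With m=7, k=4, p=0.2 it
    equals 0.033344.
    """
    if not 0 <= per_measure_rate <= 1:
        raise ValueError("per_measure_rate must be in [0, 1]")
    if not 1 <= k <= m:
        raise ValueError("need 1 <= k <= m")
    p = per_measure_rate
    return float(sum(comb(m, j) * p**j * (1 - p) ** (m - j) for j in range(k, m + 1)))
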