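"""Trial designs: weekly measurement schemes mapped onto a calendar-day grid.

A design measures a fresh cross-section of ``m`` subjects per cluster on a
fixed subset of weekdays, repeated for ``R`` consecutive weeks, in each of
``k`` clusters per treatment arm.  Day 1 of the trial is the Monday of week 1,
so the weekday ``d`` (1 = Monday .. 7 = Sunday) of week ``w`` falls on
calendar day ``7 (w - 1) + d``.  Correlation decay and dropout both operate
on this calendar-day axis, not on the index of the observed period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "WEEKDAY_NAMES",
    "WeeklyScheme",
    "TrialDesign",
    "TestSpec",
    "SchemeMixture",
    "make_design",
    "mixture",
]

#: Two-letter weekday abbreviations, index 1 = Monday .. 7 = Sunday.
WEEKDAY_NAMES = ("Mo", "Tu", "We", "Th", "Fr", "Sa", "Su")

_NAME_TO_INDEX = {name.lower(): i + 1 for i, name in enumerate(WEEKDAY_NAMES)}


class DesignError(ValueError):
    """Raised when a design specification violates its constraints."""


@dataclass(frozen=True)
class WeeklyScheme:
    """An ordered, non-empty subset of weekdays on which measurements are taken.

    Parameters
    ----------
    days
        Strictly increasing weekday indices in 1..7 (1 = Monday).
    """

    days: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise DesignError("scheme: at least one weekday is required")
        for d in self.days:
            if not isinstance(d, int) or not 1 <= d <= 7:
                raise DesignError(f"scheme: weekday index {d!r} not in 1..7")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise DesignError("scheme: weekday indices must be strictly increasing")

    @classmethod
    def from_string(cls, text: str) -> "WeeklyScheme":
        """Parse a comma-separated list of abbreviations, e.g. ``"Mo,Tu,Fr"``."""
        days = []
        for token in text.split(","):
            token = token.strip().lower()
            if token not in _NAME_TO_INDEX:
                raise DesignError(
                    f"scheme: unknown weekday {token!r}; expected one of "
                    + ",".join(WEEKDAY_NAMES)
                )
            days.append(_NAME_TO_INDEX[token])
        return cls(tuple(sorted(set(days))))

    def __len__(self) -> int:
        return len(self.days)

    def __str__(self) -> str:
        return ",".join(WEEKDAY_NAMES[d - 1] for d in self.days)


@dataclass(frozen=True)
class TrialDesign:
    """One arm-symmetric design: scheme, weeks, clusters and cluster-period size.

    Both arms share ``k``, ``m``, the scheme and ``R``; only dropout
    parameters may differ between arms.
    """

    scheme: WeeklyScheme
    weeks: int
    clusters: int
    subjects: int

    def __post_init__(self) -> None:
        if not isinstance(self.weeks, int) or self.weeks < 1:
            raise DesignError(f"weeks: must be an integer >= 1, got {self.weeks!r}")
        if not isinstance(self.clusters, int) or self.clusters < 1:
            raise DesignError(
                f"clusters: must be an integer >= 1, got {self.clusters!r}"
            )
        if not isinstance(self.subjects, int) or self.subjects < 1:
            raise DesignError(
                f"subjects: must be an integer >= 1, got {self.subjects!r}"
            )
        if self.n_periods < 2:
            raise DesignError(
                "design: measurements must be taken in at least two periods "
                f"(got {len(self.scheme)} day(s) x {self.weeks} week(s))"
            )

    @property
    def n_periods(self) -> int:
        """Total number of measurement periods T = |scheme| x R."""
        return len(self.scheme) * self.weeks

    @property
    def calendar_days(self) -> tuple[int, ...]:
        """Calendar day of each measurement period, 1-based, strictly increasing."""
        return tuple(
            7 * w + d for w in range(self.weeks) for d in self.scheme.days
        )

    @property
    def last_day(self) -> int:
        return self.calendar_days[-1]

    def with_subjects(self, m: int) -> "TrialDesign":
        """Return a copy of this design with ``m`` subjects per cluster-period."""
        return TrialDesign(self.scheme, self.weeks, self.clusters, m)


def make_design(
    scheme: WeeklyScheme | str | tuple[int, ...],
    weeks: int,
    clusters: int,
    subjects: int = 1,
) -> TrialDesign:
    """Build a :class:`TrialDesign`, accepting flexible scheme notation.

    ``scheme`` may be a :class:`WeeklyScheme`, a string such as ``"Mo,Tu,Fr"``,
    or a tuple of weekday indices.
    """
    if isinstance(scheme, str):
        scheme = WeeklyScheme.from_string(scheme)
    elif not isinstance(scheme, WeeklyScheme):
        scheme = WeeklyScheme(tuple(scheme))
    return TrialDesign(scheme, weeks, clusters, subjects)


@dataclass(frozen=True)
class TestSpec:
    """Parameters of the test on treatment effect.

    ``d`` is Cohen's standardized effect size; because the total outcome
    variance is normalized to one, the treatment effect equals ``d``.
    """

    __test__ = False  # dataclass, despite the Test* name

    d: float
    alpha: float = 0.05
    sided: str = "two"

    def __post_init__(self) -> None:
        if self.d == 0:
            raise DesignError("d: effect size must be nonzero")
        if not 0 < self.alpha < 1:
            raise DesignError(f"alpha: must be in (0, 1), got {self.alpha!r}")
        if self.sided not in ("one", "two"):
            raise DesignError(f"sided: must be 'one' or 'two', got {self.sided!r}")


@dataclass(frozen=True)
class SchemeMixture:
    """A weighted mixture of weekly schemes, e.g. clusters with differing workdays.

    Weights must be positive and sum to one.  Downstream, a mixture
    contributes ``k * w_l`` clusters under each component scheme to the
    information matrix before inversion.
    """

    components: tuple[tuple[WeeklyScheme, float], ...]

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise DesignError("mixture: at least one scheme is required")
        total = 0.0
        for scheme, w in self.components:
            if not isinstance(scheme, WeeklyScheme):
                raise DesignError("mixture: components must be WeeklyScheme objects")
            if not 0 < w <= 1:
                raise DesignError(f"mixture: weight {w!r} not in (0, 1]")
            total += w
        if abs(total - 1.0) > 1e-10:
            raise DesignError(f"mixture: weights sum to {total!r}, expected 1")

    @property
    def schemes(self) -> tuple[WeeklyScheme, ...]:
        return tuple(s for s, _ in self.components)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, w in self.components)


def mixture(components: list[tuple[WeeklyScheme | str, float]]) -> SchemeMixture:
    """Build a :class:`SchemeMixture` from ``(scheme, weight)`` pairs."""
    parsed = tuple(
        (WeeklyScheme.from_string(s) if isinstance(s, str) else s, float(w))
        for s, w in components
    )
    return SchemeMixture(parsed)
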