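"""Borda-count rank aggregation of quality indices.

Each quality index ranks the candidate algorithms; with ``N`` candidates
the best receives ``N`` points and the worst 1.  A grouping (spectral,
spatial, global) sums the points of its member indices, and algorithms
are ordered by the aggregate score.  Ties within one index are resolved
by a configurable policy; ties in the aggregate are reported jointly,
never silently broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "IndexTable",
    "BordaResult",
    "INDEX_ORIENTATIONS",
    "DEFAULT_GROUPINGS",
    "borda_points",
    "aggregate",
    "rank_report",
]

#: True = larger values are better.
INDEX_ORIENTATIONS = {
    "sam": False,
    "ergas_spectral": False,
    "ergas_spatial": False,
    "fc": True,
    "zhou": True,
    "q": True,
}

#: Default index groupings.  The spatial grouping is the [FC, Zhou] pair;
#: the three-index variant including spatial ERGAS is available by passing
#: an explicit grouping.
DEFAULT_GROUPINGS = {
    "spectral": ["sam", "ergas_spectral"],
    "spatial": ["fc", "zhou"],
    "global": ["sam", "ergas_spectral", "ergas_spatial", "fc", "zhou", "q"],
}

_TIE_POLICIES = ("high", "low", "average")


@dataclass
class IndexTable:
    """Per-algorithm values for a set of quality indices.

    ``values[item][index_name]`` holds the raw index value; orientations
    default to :data:`INDEX_ORIENTATIONS`.
    """

    values: dict[str, dict[str, float]]
    orientations: dict[str, bool] = field(default_factory=lambda: dict(INDEX_ORIENTATIONS))

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("IndexTable requires at least one item")
        names = None
        for item, row in self.values.items():
            keys = set(row)
            if names is None:
                names = keys
            elif keys != names:
                raise ValueError(f"item {item!r} is missing index values")
        for name in names or ():
            if name not in self.orientations:
                raise ValueError(f"no orientation declared for index {name!r}")

    @property
    def items(self) -> list[str]:
        return list(self.values)

    @property
    def index_names(self) -> list[str]:
        return list(next(iter(self.values.values())))

    def column(self, index_name: str) -> dict[str, float]:
        return {item: row[index_name] for item, row in self.values.items()}

    @classmethod
    def from_reports(cls, reports: dict[str, "object"]) -> "IndexTable":
        """Build from ``{algorithm: QualityReport}`` (one subset each)."""
        values = {}
        for name, rep in reports.items():
            values[name] = {
                "sam": rep.sam_deg,
                "ergas_spectral": rep.ergas_spectral,
                "ergas_spatial": rep.ergas_spatial,
                "fc": rep.fc,
                "zhou": rep.zhou,
                "q": rep.q_global,
            }
        return cls(values)


@dataclass
class BordaResult:
    """Per-index Borda points, aggregate scores per grouping, and the
    policies that produced them."""

    points: dict[str, dict[str, float]]  # index -> item -> points
    scores: dict[str, dict[str, float]]  # grouping -> item -> score
    tie_policy: str
    groupings: dict[str, list[str]]

    def to_frame(self) -> pd.DataFrame:
        """Aggregate scores as a DataFrame (items x groupings)."""
        return pd.DataFrame(self.scores)


def borda_points(values: dict[str, float], higher_better: bool,
                 tie_policy: str = "high") -> dict[str, float]:
    """Borda points for one index: with ``N`` items the best gets ``N``
    points and the worst 1.

    Tied items contest a run of consecutive ranks; the policy awards all
    of them the best contested rank's points (``high``), the worst
    (``low``) or the arithmetic mean (``average``).
    """
    if not values:
        raise ValueError("borda_points requires a non-empty value map")
    if len(values) < 2:
        raise ValueError("borda_points requires at least 2 items")
    if tie_policy not in _TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {_TIE_POLICIES}")
    n = len(values)
    # sort best-first; points for position p (0-based) are n - p
    ordered = sorted(values.items(), key=lambda kv: kv[1], reverse=higher_better)
    points: dict[str, float] = {}
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ordered[j + 1][1] == ordered[i][1]:
            j += 1
        contested = [n - p for p in range(i, j + 1)]
        if tie_policy == "high":
            award = float(max(contested))
        elif tie_policy == "low":
            award = float(min(contested))
        else:
            award = float(sum(contested)) / len(contested)
        for k in range(i, j + 1):
            points[ordered[k][0]] = award
        i = j + 1
    return points


def aggregate(table: IndexTable,
              groupings: dict[str, list[str]] | None = None,
              tie_policy: str = "high") -> BordaResult:
    """Borda aggregation: per-grouping scores are the exact sums of the
    member indices' points."""
    if groupings is None:
        groupings = {k: list(v) for k, v in DEFAULT_GROUPINGS.items()}
    available = set(table.index_names)
    for gname, members in groupings.items():
        if not members:
            raise ValueError(f"grouping {gname!r} is empty")
        missing = [m for m in members if m not in available]
        if missing:
            raise ValueError(f"grouping {gname!r} references unknown indices {missing}")
    points = {
        name: borda_points(table.column(name), table.orientations[name], tie_policy)
        for name in table.index_names
    }
    scores = {
        gname: {item: float(sum(points[m][item] for m in members))
                for item in table.items}
        for gname, members in groupings.items()
    }
    return BordaResult(points=points, scores=scores, tie_policy=tie_policy,
                       groupings={k: list(v) for k, v in groupings.items()})


def rank_report(result: BordaResult) -> dict[str, list[list[str]]]:
    """Ordered listing per grouping: a list of rank groups, best first;
    algorithms with equal aggregate score share a rank group (ties are
    reported jointly, never silently broken)."""
    if not result.scores:
        raise ValueError("empty Borda result")
    report: dict[str, list[list[str]]] = {}
    for gname, scores in result.scores.items():
        by_score: dict[float, list[str]] = {}
        for item, s in scores.items():
            by_score.setdefault(s, []).append(item)
        report[gname] = [sorted(by_score[s]) for s in sorted(by_score, reverse=True)]
    return report
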