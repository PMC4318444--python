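"""Treatment-comparison statistics over trait time courses.

Two analyses mirror how such growth experiments are read out: a
two-sample t-test per timepoint (Welch by default — "t-test" alone does
not promise equal variances), reporting the first day the treatment
separates from the mock; and a Pearson correlation between two traits
across plants (e.g. harvest biomass vs projected root surface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imgio import TraitRecord, records_to_frame

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "first_significant_timepoint",
    "correlate_traits",
    "holm_adjust",
]


@dataclass
class ComparisonResult:
    """Welch t-test of one trait between two treatments at one timepoint."""

    trait_name: str
    timepoint: int
    groups: tuple[str, str]
    group_means: tuple[float, float]
    group_sizes: tuple[int, int]
    t_statistic: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _as_frame(records: Iterable[TraitRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def _welch(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    # guard the degenerate zero-variance cases scipy maps to nan
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_groups(records: Iterable[TraitRecord] | pd.DataFrame,
                   trait: str,
                   alpha: float = 0.05,
                   equal_var: bool = False,
                   groups: Sequence[str] | None = None,
                   ) -> list[ComparisonResult]:
    """Per-timepoint two-sample t-tests of one trait between two treatments.

    Exactly two treatment groups must be present overall; timepoints where
    either group is missing or has fewer than two plants are skipped with
    a warning.  Results come back sorted by timepoint.
    """
    df = _as_frame(records)
    df = df[df["trait_name"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    found = sorted(df["treatment"].unique())
    if groups is None:
        if len(found) != 2:
            raise ValueError(f"need exactly two treatment groups, found {found}")
        groups = found
    g1, g2 = groups

    out: list[ComparisonResult] = []
    for tp, sub in df.groupby("timepoint"):
        a = sub.loc[sub["treatment"] == g1, "value"].to_numpy(float)
        b = sub.loc[sub["treatment"] == g2, "value"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"timepoint {tp}: group missing or n < 2, skipped")
            continue
        t, p = _welch(a, b, equal_var)
        out.append(ComparisonResult(
            trait_name=trait,
            timepoint=int(tp),
            groups=(g1, g2),
            group_means=(float(a.mean()), float(b.mean())),
            group_sizes=(len(a), len(b)),
            t_statistic=t,
            p_value=p,
            alpha=alpha,
        ))
    out.sort(key=lambda r: r.timepoint)
    return out


def first_significant_timepoint(results: Sequence[ComparisonResult]) -> int | None:
    """Earliest timepoint with p < alpha, or None ("6 DAT"-style readout)."""
    for r in results:
        if r.significant:
            return r.timepoint
    return None


def holm_adjust(results: Sequence[ComparisonResult]) -> list[ComparisonResult]:
    """Holm step-down adjusted copies of the results (off by default in
    the per-day readout, provided for stricter family-wise control)."""
    order = np.argsort([r.p_value for r in results])
    m = len(results)
    adjusted = [None] * m
    running = 0.0
    for rank, idx in enumerate(order):
        p = min(max((m - rank) * results[idx].p_value, running), 1.0)
        running = p
        r = results[idx]
        adjusted[idx] = ComparisonResult(r.trait_name, r.timepoint, r.groups,
                                         r.group_means, r.group_sizes,
                                         r.t_statistic, p, r.alpha)
    return adjusted


def correlate_traits(records: Iterable[TraitRecord] | pd.DataFrame,
                     trait_x: str,
                     trait_y: str,
                     timepoint: int | None = None) -> tuple[float, int]:
    """Pearson r between two traits paired per plant.

    Pairs match on plant id (and timepoint unless a single timepoint is
    selected).  Raises when fewer than three pairs exist or either trait
    has zero variance (correlation undefined).
    """
    df = _as_frame(records)
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint]
        keys = ["plant_id"]
    else:
        keys = ["plant_id", "timepoint"]
    x = df[df["trait_name"] == trait_x].set_index(keys)["value"]
    y = df[df["trait_name"] == trait_y].set_index(keys)["value"]
    joined = pd.concat([x, y], axis=1, join="inner", keys=["x", "y"]).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if joined["x"].std() == 0 or joined["y"].std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = sps.pearsonr(joined["x"], joined["y"])
    return float(r), n
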