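"""Peak-table ingestion, area normalization and group statistics.

The quantitative unit of a CHC study is the *relative percentage*: each
individual's peak areas are normalised to sum to 100 (area
normalization), making profiles compositional.  This module turns
per-individual peak tables into an individuals x components
:class:`ProfileMatrix`, summarises groups (mean +/- SE), computes
class-level compositions, and runs the univariate contrasts used for
single components: a two-sample t-test between sexes and one-way ANOVA
with a Student-Newman-Keuls (SNK) post hoc letter display across
populations.

A component reported *nd* (not detected) is stored as an exact zero
with a detection flag -- absence, not missingness -- so downstream
distances and ordinal coding treat it as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compounds import parse_component_name

__all__ = [
    "PeakTable",
    "ProfileMatrix",
    "TTestResult",
    "AnovaResult",
    "normalize",
    "build_profile_matrix",
    "profile_matrix_from_percentages",
    "group_summary",
    "class_composition",
    "class_composition_from_means",
    "sex_contrast",
    "multi_group_contrast",
    "snk_letters",
    "read_peak_tables_csv",
    "write_peak_tables_csv",
]


@dataclass
class PeakTable:
    """GC-MS peak table for one individual.

    ``rows`` is a DataFrame with columns ``component``, ``rt_min``,
    ``area`` (raw integrated areas, >= 0).
    """

    individual_id: str
    population: str
    sex: str  # "male" / "female" / "unknown"
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"component", "rt_min", "area"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        if self.rows["component"].duplicated().any():
            dups = self.rows.loc[self.rows["component"].duplicated(), "component"]
            raise ValueError(f"duplicate components for {self.individual_id}: {list(dups)}")
        if (self.rows["area"] < 0).any():
            raise ValueError("negative peak areas")


def normalize(pt: PeakTable) -> pd.Series:
    """Relative percentages by area normalization: 100*area_i / sum(area)."""
    areas = pt.rows.set_index("component")["area"].astype(float)
    total = areas.sum()
    if total <= 0:
        raise ValueError(f"{pt.individual_id}: all peak areas are zero")
    return 100.0 * areas / total


@dataclass
class ProfileMatrix:
    """Individuals x components matrix of relative percentages.

    ``values``: DataFrame (rows = individuals, columns = components),
    each row summing to 100.  ``meta``: per-individual ``population``
    and ``sex``.  ``detected``: boolean mask; an exact-zero entry with
    ``detected=False`` is an *nd* record.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    detected: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.detected is None:
            self.detected = self.values > 0
        if (self.values.values < 0).any():
            raise ValueError("negative percentages")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 100.0, atol=1e-9)]
            raise ValueError(f"rows do not sum to 100: {bad.to_dict()}")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta indices differ")

    @property
    def components(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, mask) -> "ProfileMatrix":
        return ProfileMatrix(
            self.values.loc[mask], self.meta.loc[mask], self.detected.loc[mask]
        )


def build_profile_matrix(
    tables: Sequence[PeakTable], components: Optional[Sequence[str]] = None
) -> ProfileMatrix:
    """Assemble normalised individual profiles into a ProfileMatrix.

    ``components`` fixes the column set/order (absent components become
    nd zeros); defaults to the union of observed components in first-
    appearance order.
    """
    if not tables:
        raise ValueError("no peak tables given")
    if components is None:
        seen: dict[str, None] = {}
        for pt in tables:
            for comp in pt.rows["component"]:
                seen.setdefault(comp, None)
        components = list(seen)
    rows, meta_rows, det_rows = [], [], []
    for pt in tables:
        pct = normalize(pt).reindex(components)
        det_rows.append(pct.notna() & (pct > 0))
        rows.append(pct.fillna(0.0))
        meta_rows.append({"population": pt.population, "sex": pt.sex})
    values = pd.DataFrame(rows, index=[pt.individual_id for pt in tables])
    meta = pd.DataFrame(meta_rows, index=values.index)
    detected = pd.DataFrame(det_rows, index=values.index)
    return ProfileMatrix(values, meta, detected)


def profile_matrix_from_percentages(
    values: pd.DataFrame, meta: pd.DataFrame, detected: Optional[pd.DataFrame] = None
) -> ProfileMatrix:
    """Accept percentage-only input; rows are renormalised to sum to 100."""
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("zero-sum profile row")
    renorm = values.div(sums, axis=0) * 100.0
    if detected is None:
        detected = values > 0
    return ProfileMatrix(renorm, meta, detected)


def group_summary(m: ProfileMatrix, by: str = "population") -> pd.DataFrame:
    """Per-group per-component mean, SE (of the mean) and n.

    Returns a DataFrame with MultiIndex columns ``(group, stat)`` where
    stat is ``mean`` / ``se`` / ``n``, indexed by component.
    """
    groups = m.meta[by]
    out = {}
    for g, idx in m.values.groupby(groups).groups.items():
        sub = m.values.loc[idx]
        n = len(sub)
        mean = sub.mean(axis=0)
        se = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else mean * 0.0
        out[(g, "mean")] = mean
        out[(g, "se")] = se
        out[(g, "n")] = pd.Series(float(n), index=m.values.columns)
    df = pd.DataFrame(out)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=[by, "stat"])
    return df


def class_composition_from_means(means: pd.Series) -> pd.Series:
    """Sum mean component percentages into the four structural classes."""
    classes = [parse_component_name(lbl).chc_class for lbl in means.index]
    return means.groupby(pd.Index(classes, name="chc_class")).sum()


def class_composition(m: ProfileMatrix, group: str, by: str = "population") -> pd.Series:
    """Class-level composition (sums of group mean component percentages)."""
    groups = m.meta[by]
    if group not in set(groups):
        raise KeyError(f"unknown group {group!r} for {by!r}")
    means = m.values.loc[groups == group].mean(axis=0)
    return class_composition_from_means(means)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    direction: str  # group label with the larger mean ("" if tied)
    significant_05: bool
    significant_01: bool
    n: tuple[int, int]


def sex_contrast(
    m: ProfileMatrix, component: str, *, equal_var: bool = True
) -> TTestResult:
    """Two-sample t-test of one component's percentage between sexes.

    Student's (equal-variance) t by default; ``equal_var=False`` gives
    Welch's test.
    """
    sex = m.meta["sex"]
    a = m.values.loc[sex == "male", component].to_numpy(float)
    b = m.values.loc[sex == "female", component].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both sexes need n >= 2")
    stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(stat):  # zero variance in both groups, identical means
        stat, p = 0.0, 1.0
    direction = "male" if a.mean() > b.mean() else "female" if b.mean() > a.mean() else ""
    return TTestResult(float(stat), float(p), direction, p < 0.05, p < 0.01, (len(a), len(b)))


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    letters: dict[str, str]  # compact letter display; shared letter = not separated
    group_means: dict[str, float]
    alpha: float


def snk_letters(
    means: pd.Series, ns: pd.Series, mse: float, df_error: int, alpha: float = 0.05
) -> dict[str, str]:
    """Student-Newman-Keuls stepwise range test with compact letters.

    Groups are ordered by mean; a stretch of ``p`` ordered means is
    declared homogeneous when its range falls below
    ``q(1-alpha, p, df) * sqrt(MSE/2 * (1/n_i + 1/n_j))`` (Kramer
    adjustment for unequal n), testing stepwise from the full range
    inward.  Groups share a letter iff they lie in a common homogeneous
    stretch.  Letters are invariant to group relabeling because they
    depend only on the ordered means.
    """
    order = means.sort_values(ascending=False).index
    k = len(order)
    if k == 1:
        return {order[0]: "a"}
    homogeneous: list[tuple[int, int]] = []

    def test(i: int, j: int) -> None:
        if i >= j:
            return
        p = j - i + 1
        gi, gj = order[i], order[j]
        crit = stats.studentized_range.ppf(1 - alpha, p, df_error)
        se = np.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
        if se == 0:
            significant = means[gi] - means[gj] > 1e-12
        else:
            significant = (means[gi] - means[gj]) > crit * se
        if significant:
            test(i + 1, j)
            test(i, j - 1)
        else:
            homogeneous.append((i, j))

    test(0, k - 1)
    # maximal homogeneous stretches -> letters; singletons get their own
    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in homogeneous)
    ]
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    for i in range(k):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()
    letters: dict[str, list[str]] = {g: [] for g in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, (i, j) in zip(alphabet, maximal):
        for idx in range(i, j + 1):
            letters[order[idx]].append(letter)
    return {g: "".join(v) for g, v in letters.items()}


def multi_group_contrast(
    m: ProfileMatrix, component: str, by: str = "population", alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA across groups with an SNK letter display."""
    groups = m.meta[by]
    samples = {
        g: m.values.loc[idx, component].to_numpy(float)
        for g, idx in m.values.groupby(groups).groups.items()
    }
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in samples.values()):
        raise ValueError("every group needs n >= 2")
    arrays = list(samples.values())
    n_total = sum(len(v) for v in arrays)
    k = len(arrays)
    df_error = n_total - k
    mse = sum((len(v) - 1) * np.var(v, ddof=1) for v in arrays) / df_error
    if np.allclose([v.mean() for v in arrays], arrays[0].mean()) and mse == 0:
        # all observations identical: no separation, single shared letter
        letters = {g: "a" for g in samples}
        return AnovaResult(0.0, 1.0, letters, {g: float(v.mean()) for g, v in samples.items()}, alpha)
    if mse == 0:
        raise ValueError("degenerate within-group variance")
    f, p = stats.f_oneway(*arrays)
    means = pd.Series({g: v.mean() for g, v in samples.items()})
    ns = pd.Series({g: len(v) for g, v in samples.items()})
    letters = snk_letters(means, ns, mse, df_error, alpha)
    return AnovaResult(float(f), float(p), letters, means.to_dict(), alpha)


# ---------------------------------------------------------------------------
# CSV dialect: individual,population,sex,component,rt_min,area

def read_peak_tables_csv(path) -> list[PeakTable]:
    """Read the long-format peak-table CSV into per-individual tables."""
    df = pd.read_csv(path)
    required = {"individual", "population", "sex", "component", "rt_min", "area"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak-table CSV needs columns {sorted(required)}")
    tables = []
    for ind, sub in df.groupby("individual", sort=False):
        tables.append(
            PeakTable(
                individual_id=str(ind),
                population=str(sub["population"].iloc[0]),
                sex=str(sub["sex"].iloc[0]),
                rows=sub[["component", "rt_min", "area"]].reset_index(drop=True),
            )
        )
    return tables


def write_peak_tables_csv(tables: Iterable[PeakTable], path) -> None:
    frames = []
    for pt in tables:
        sub = pt.rows.copy()
        sub.insert(0, "individual", pt.individual_id)
        sub.insert(1, "population", pt.population)
        sub.insert(2, "sex", pt.sex)
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
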