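"""Distance-based comparison of CHC profiles.

Individual-level analyses work on relative percentages (not ordinal
codes): Bray-Curtis dissimilarity, non-metric multidimensional scaling
(NMDS, Kruskal stress-1), one-way PERMANOVA with freely permuted
labels, and UPGMA clustering of individuals.

PERMANOVA follows Anderson's distance-based formulation.  For a one-way
design the among/within sums of squares obtained by Gower-centering the
squared distance matrix reduce to

    SS_total  = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    pseudo-F  = (SS_among / (k-1)) / (SS_within / (n-k))

with the p-value from free permutation of group labels,
p = (b + 1) / (n_perm + 1).  Given a seed the permutation stream, and
hence the p-value, is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profiles import ProfileMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "bray_curtis",
    "bray_curtis_from_values",
    "nmds",
    "permanova",
    "hierarchical_cluster",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with item labels."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("negative dissimilarities")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(df.to_numpy(dtype=float), tuple(str(i) for i in df.index))

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=list(self.ids))


def bray_curtis_from_values(values: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis d(a,b) = sum|a_i - b_i| / sum(a_i + b_i) over rows."""
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    if (arr.sum(axis=1) <= 0).any():
        raise ValueError("zero-sum row")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(d, tuple(str(i) for i in values.index))


def bray_curtis(m: ProfileMatrix) -> DistanceMatrix:
    """Bray-Curtis distances between individual relative-percentage profiles."""
    return bray_curtis_from_values(m.values)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # items x k
    stress: float  # Kruskal stress-1
    k: int
    restarts: int
    seed: int
    converged: bool


def nmds(
    d: DistanceMatrix, k: int = 2, restarts: int = 20, seed: int = 0
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1, best of ``restarts`` starts."""
    from sklearn.manifold import MDS

    if k < 1:
        raise ValueError("k must be >= 1")
    model = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
    )
    coords = model.fit_transform(d.values)
    converged = bool(np.isfinite(coords).all() and np.isfinite(model.stress_))
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(frame, float(model.stress_), k, restarts, seed, converged)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: Optional[int]


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    """SS_within for integer group codes (d2 = squared distance matrix)."""
    ss_w = 0.0
    for g, n_g in enumerate(counts):
        mask = codes == g
        ss_w += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss_w


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with label permutation."""
    labels = pd.Series(list(groups))
    if len(labels) != len(d):
        raise ValueError("group labels do not match distance matrix size")
    codes, uniques = pd.factorize(labels)
    k = len(uniques)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs n >= 2")
    n = len(labels)
    d2 = d.values ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _permanova_ss(d2, codes, counts)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (k - 1)) / (ss_within / (n - k))
    r2 = ss_among / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ss_w = _permanova_ss(d2, perm, counts)
        ss_a = ss_total - ss_w
        f_perm = (ss_a / (k - 1)) / (ss_w / (n - k))
        if f_perm >= f_obs:
            b += 1
    p = (b + 1) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, seed)


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "upgma"):
    """UPGMA dendrogram over the items of ``d`` (see chemotaxonomy.upgma)."""
    if linkage != "upgma":
        raise ValueError("only UPGMA linkage is supported")
    from .chemotaxonomy import upgma

    return upgma(d)
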