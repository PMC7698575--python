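"""Permutation inference on distance matrices, plus ANOVA for growth traits.

Implements the statistical machinery used on per-fish pigmentation
features:

- Manhattan/Euclidean distance matrices over a feature table;
- one-way ANOSIM (Clarke's rank-based R with a label-permutation null);
- two-way crossed ANOSIM: the R of one factor is computed within each
  stratum (level) of the other factor and averaged, and permutations are
  restricted to strata;
- pairwise one-way ANOSIMs with Bonferroni correction;
- the Mantel test of association between two distance matrices
  (Spearman by default), permuting rows and columns of one matrix jointly;
- classical one-way ANOVA with Tukey HSD and a compact letter display.

All permutation p-values use the +1 convention,
``p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)``, so the smallest
attainable p is 1/(n_perm+1) and p is never zero. Ties in ranks are
resolved by average ranks throughout. Every stochastic routine is
reproducible from (seed, n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import rankdata, studentized_range

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "AnosimResult",
    "TwoWayAnosimResult",
    "MantelResult",
    "AnovaResult",
    "distance_matrix",
    "anosim",
    "anosim_twoway",
    "anosim_pairwise",
    "mantel",
    "anova_tukey",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance structure over labelled individuals."""

    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.n, 1)
        return self.d[iu, ju]

    def submatrix(self, idx: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(idx, dtype=int)
        return DistanceMatrix(
            tuple(self.labels[i] for i in idx), self.d[np.ix_(idx, idx)]
        )


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    per_stratum_R: list[float] | None = None
    pairwise: pd.DataFrame | None = None


@dataclass
class TwoWayAnosimResult:
    factor_a: AnosimResult
    factor_b: AnosimResult


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    correlation: str


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame
    letters: dict


def distance_matrix(
    X: np.ndarray | pd.DataFrame,
    metric: Literal["manhattan", "euclidean"] = "manhattan",
    labels: Sequence | None = None,
) -> DistanceMatrix:
    """Pairwise distances over an n x k feature table.

    Rows containing missing values are dropped with a logged warning
    before computing distances.
    """
    if isinstance(X, pd.DataFrame):
        if labels is None:
            labels = list(X.index)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and labels is not None:
            X = X.T
    if X.ndim == 1:
        X = X[:, None]
    if labels is None:
        labels = list(range(X.shape[0]))
    labels = list(labels)

    keep = ~np.isnan(X).any(axis=1)
    if not keep.all():
        dropped = [labels[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d rows with missing features: %s", len(dropped), dropped)
        X = X[keep]
        labels = [labels[i] for i in np.flatnonzero(keep)]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two complete rows")

    diff = X[:, None, :] - X[None, :, :]
    if metric == "manhattan":
        d = np.abs(diff).sum(axis=2)
    elif metric == "euclidean":
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(labels), d)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class _OneWayEngine:
    """Precomputed rank structure for fast repeated ANOSIM R evaluation."""

    def __init__(self, d: np.ndarray):
        n = d.shape[0]
        self.iu, self.ju = np.triu_indices(n, 1)
        self.ranks = rankdata(d[self.iu, self.ju])
        self.M = self.ranks.size
        self.S = self.ranks.sum()

    def R(self, codes: np.ndarray) -> float:
        same = codes[self.iu] == codes[self.ju]
        nw = int(same.sum())
        sw = self.ranks[same].sum()
        rw = sw / nw
        rb = (self.S - sw) / (self.M - nw)
        return (rb - rw) / (self.M / 2)


def _codes(groups: Sequence) -> np.ndarray:
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes


def _check_groups(codes: np.ndarray, min_groups: int = 2) -> None:
    counts = np.bincount(codes)
    if len(counts) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(counts)}")
    if (counts < 2).any():
        raise ValueError("every group must have at least 2 members")


def anosim(
    dm: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed=None,
) -> AnosimResult:
    """One-way ANOSIM.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 ranks over all dissimilarities; the null distribution
    comes from uniform permutations of the group labels.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = _codes(groups)
    if len(codes) != dm.n:
        raise ValueError("groups length must match distance matrix size")
    _check_groups(codes)
    eng = _OneWayEngine(dm.d)
    r_obs = eng.R(codes)
    rng = _as_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if eng.R(perm) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(R=float(r_obs), p=float(p), n_permutations=n_perm)


class _StratifiedEngine:
    """Per-stratum one-way engines for the crossed two-way design."""

    def __init__(self, dm: DistanceMatrix, codes: np.ndarray, strata: np.ndarray):
        self.strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        self.engines = []
        self.codes = []
        for idx in self.strata_idx:
            sub_codes = codes[idx]
            uniq, sub_codes = np.unique(sub_codes, return_inverse=True)
            if len(uniq) < 2:
                raise ValueError("a stratum has fewer than 2 groups of the tested factor")
            if (np.bincount(sub_codes) < 2).any():
                raise ValueError("a within-stratum group has fewer than 2 members")
            self.engines.append(_OneWayEngine(dm.d[np.ix_(idx, idx)]))
            self.codes.append(sub_codes)

    def observed(self) -> tuple[float, list[float]]:
        rs = [eng.R(c) for eng, c in zip(self.engines, self.codes)]
        return float(np.mean(rs)), [float(r) for r in rs]

    def permuted(self, rng: np.random.Generator) -> float:
        rs = [eng.R(rng.permutation(c)) for eng, c in zip(self.engines, self.codes)]
        return float(np.mean(rs))


def _anosim_stratified(
    dm: DistanceMatrix,
    factor: Sequence,
    strata: Sequence,
    n_perm: int,
    rng: np.random.Generator,
) -> AnosimResult:
    codes = _codes(factor)
    strata_codes = _codes(strata)
    eng = _StratifiedEngine(dm, codes, strata_codes)
    r_obs, per_stratum = eng.observed()
    count = 0
    for _ in range(n_perm):
        if eng.permuted(rng) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(
        R=r_obs, p=float(p), n_permutations=n_perm, per_stratum_R=per_stratum
    )


def anosim_twoway(
    dm: DistanceMatrix,
    factor_a: Sequence,
    factor_b: Sequence,
    n_perm: int = 999,
    seed=None,
    n_perm_b: int | None = None,
) -> TwoWayAnosimResult:
    """Two-way crossed ANOSIM for both factors.

    For factor A the one-way R is computed within every level of B and
    averaged; the permutation null shuffles A labels independently within
    each stratum of B (and symmetrically for factor B). Every (a, b) cell
    must be nonempty with enough replication for a within-stratum one-way
    test.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if len(factor_a) != dm.n or len(factor_b) != dm.n:
        raise ValueError("factor lengths must match distance matrix size")
    rng = _as_rng(seed)
    res_a = _anosim_stratified(dm, factor_a, factor_b, n_perm, rng)
    res_b = _anosim_stratified(
        dm, factor_b, factor_a, n_perm_b if n_perm_b is not None else n_perm, rng
    )
    return TwoWayAnosimResult(factor_a=res_a, factor_b=res_b)


def anosim_pairwise(
    dm: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed=None,
) -> pd.DataFrame:
    """One one-way ANOSIM per unordered pair of groups, Bonferroni-adjusted."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 3:
        raise ValueError("pairwise post-hocs need at least 3 groups")
    n_pairs = len(uniq) * (len(uniq) - 1) // 2
    rng = _as_rng(seed)
    rows = []
    for g1, g2 in combinations(uniq, 2):
        idx = np.flatnonzero((groups == g1) | (groups == g2))
        res = anosim(dm.submatrix(idx), groups[idx], n_perm=n_perm, seed=rng)
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "R": res.R,
                "p_raw": res.p,
                "p_bonferroni": min(1.0, res.p * n_pairs),
            }
        )
    return pd.DataFrame(rows)


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    correlation: Literal["spearman", "pearson"] = "spearman",
    n_perm: int = 9999,
    seed=None,
) -> MantelResult:
    """Mantel test of matrix association.

    The statistic is the (Spearman or Pearson) correlation between the
    upper triangles; the null permutes rows and columns of ``dm_b``
    jointly. The one-sided p-value counts permuted correlations at least
    as large as the observed one.
    """
    if dm_a.labels != dm_b.labels:
        raise ValueError("distance matrices must share the same labels in order")
    n = dm_a.n
    if n < 3:
        raise ValueError("Mantel test needs at least 3 objects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    iu, ju = np.triu_indices(n, 1)
    a = dm_a.d[iu, ju]
    b = dm_b.d[iu, ju]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant upper triangle: correlation undefined")

    if correlation == "spearman":
        a_vals = rankdata(a)
        b_mat = np.zeros((n, n))
        b_mat[iu, ju] = rankdata(b)
        b_mat += b_mat.T
    elif correlation == "pearson":
        a_vals = a
        b_mat = dm_b.d
    else:
        raise ValueError(f"unknown correlation {correlation!r}")

    # Under a joint row/column permutation the triangle multiset of b is
    # preserved, so its centering and scale are permutation constants.
    ca = a_vals - a_vals.mean()
    norm_a = np.sqrt((ca**2).sum())
    b_tri = b_mat[iu, ju]
    mean_b = b_tri.mean()
    norm_b = np.sqrt(((b_tri - mean_b) ** 2).sum())

    def corr_with(b_vec: np.ndarray) -> float:
        return float(ca @ (b_vec - mean_b) / (norm_a * norm_b))

    r_obs = corr_with(b_tri)
    rng = _as_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr_with(b_mat[p[iu], p[ju]]) >= r_obs:
            count += 1
    pval = (1 + count) / (1 + n_perm)
    return MantelResult(
        r=r_obs, p=float(pval), n_permutations=n_perm, correlation=correlation
    )


def _compact_letter_display(
    ordered_groups: list, significant: set[tuple]
) -> dict:
    """Insertion-absorption compact letter display.

    Groups sharing a letter are not significantly different. ``significant``
    holds unordered pairs found different; letters follow the group order
    given (conventionally ascending mean).
    """
    columns: list[set] = [set(ordered_groups)]
    for pair in significant:
        i, j = pair
        new_columns = []
        for col in columns:
            if i in col and j in col:
                new_columns.append(col - {i})
                new_columns.append(col - {j})
            else:
                new_columns.append(col)
        # absorb columns that are subsets of others
        columns = []
        for col in new_columns:
            if not any(col < other for other in new_columns if col is not other):
                if col not in columns:
                    columns.append(col)
    # deterministic letter order: by first ordered group each column contains
    pos = {g: k for k, g in enumerate(ordered_groups)}
    columns.sort(key=lambda col: min(pos[g] for g in col) if col else len(pos))
    letters = {g: "" for g in ordered_groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def anova_tukey(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc and compact letter display.

    The Tukey p-value for a pair uses the studentized range distribution
    with the Tukey-Kramer standard error for unequal group sizes.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    group_vals = [values[groups == g] for g in uniq]
    ns = np.array([len(v) for v in group_vals])
    if (ns < 2).any():
        raise ValueError("every group needs at least 2 observations")
    N = ns.sum()
    means = np.array([v.mean() for v in group_vals])
    grand = values.mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((v - m) ** 2).sum() for v, m in zip(group_vals, means)))
    df_b, df_w = k - 1, int(N - k)
    if ssw == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    mse = ssw / df_w
    F = (ssb / df_b) / mse
    p = float(f_dist.sf(F, df_b, df_w))

    rows = []
    significant = set()
    for (i, gi), (j, gj) in combinations(enumerate(uniq), 2):
        se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
        q = abs(means[i] - means[j]) / se
        p_ij = float(studentized_range.sf(q, k, df_w))
        if p_ij < alpha:
            significant.add((gi, gj))
        rows.append(
            {
                "group_1": gi,
                "group_2": gj,
                "mean_diff": float(means[j] - means[i]),
                "q": float(q),
                "p_tukey": p_ij,
                "significant": p_ij < alpha,
            }
        )
    order = [g for _, g in sorted(zip(means, uniq), key=lambda t: t[0])]
    letters = _compact_letter_display(order, significant)
    return AnovaResult(
        F=float(F),
        p=p,
        df_between=df_b,
        df_within=df_w,
        tukey=pd.DataFrame(rows),
        letters=letters,
    )
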