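"""Compositional statistics: log-ratio transforms, tests, and clustering.

Relative abundances are compositions (non-negative parts closed to 1), so
raw fractions are not directly comparable across samples — the constant-sum
constraint induces spurious negative correlation.  Following Aitchison's
log-ratio methodology, this module provides:

* **Zero replacement** (multiplicative): detection zeros are replaced by a
  small delta and the positive parts rescaled so closure and the ratios
  among originally positive parts are preserved.  The default delta for a
  feature is 0.65 x the smallest positive fraction observed for that feature
  across the whole dataset.
* **2-part alr**: for a single form with fraction x, the balance against all
  other forms is ``log2(x / (1 - x))``.
* **Group comparison**: two-sided two-sample t-tests on alr values (Student's
  pooled-variance by default, Welch behind a flag) with a two-tier readout:
  *significant* for p < 0.05 and *trend* for 0.05 <= p < 0.1.  No
  multiple-testing correction is applied to the tiers; Benjamini-Hochberg
  q-values are reported in a clearly separated column.
* **Pivot coordinates**: the isometric log-ratio basis in which Euclidean
  distance between coordinate vectors equals the Aitchison distance between
  compositions (natural log; coordinate values, but not distances, depend on
  the pivot order).
* **UPGMA clustering** of sample PTM profiles on Euclidean distances between
  pivot-coordinate rows, with deterministic lowest-pair-index tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .regions import ValidationError

logger = logging.getLogger("histoptm")

SIGNIFICANT_P = 0.05
TREND_P = 0.10


def significance_tier(p: float) -> str:
    """Two-tier significance readout: significant / trend / ns."""
    if p < SIGNIFICANT_P:
        return "significant"
    if p < TREND_P:
        return "trend"
    return "ns"


# ---------------------------------------------------------------------------
# zero replacement and alr


def zero_replace(
    composition: Sequence[float],
    delta: float,
    strategy: str = "multiplicative",
) -> np.ndarray:
    """Replace zero parts by *delta*, rescaling positive parts multiplicatively.

    With z zeros, each zero becomes delta and the positive parts are rescaled
    by ``(1 - z*delta) / sum(positive)``; the output is closed to 1 and the
    ratios among originally positive parts are unchanged.
    """
    if strategy != "multiplicative":
        raise ValidationError(f"unknown zero-replacement strategy {strategy!r}")
    x = np.asarray(composition, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("composition must be a vector with >= 2 parts")
    if (x < 0).any():
        raise ValidationError("negative part in composition")
    zeros = x == 0
    if zeros.all():
        raise ValidationError("all-zero composition cannot be replaced")
    if not zeros.any():
        return x.copy()
    z = int(zeros.sum())
    if not 0 < delta < 1 / x.size:
        raise ValidationError(f"delta {delta} unreasonable for {x.size} parts")
    out = np.empty_like(x)
    out[zeros] = delta
    pos_sum = x[~zeros].sum()
    out[~zeros] = x[~zeros] * (1.0 - z * delta) / pos_sum
    return out


def default_delta(observed: Iterable[float], factor: float = 0.65) -> float:
    """Delta rule: *factor* x smallest positive observed fraction."""
    positives = [v for v in observed if v > 0]
    if not positives:
        raise ValidationError("no positive observations to derive delta from")
    return factor * min(positives)


def alr2(x: float) -> float:
    """2-part additive log-ratio: ``log2(x / (1 - x))`` for x in (0, 1)."""
    if not 0 < x < 1:
        raise ValidationError(f"alr2 requires 0 < x < 1, got {x}")
    return float(np.log2(x / (1.0 - x)))


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class StatResult:
    """Result of one two-group comparison of a feature on the alr scale."""

    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_alr_a: float
    mean_alr_b: float
    t_statistic: float
    p_value: float
    tier: str


def group_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    feature: str = "",
    group_a: str = "a",
    group_b: str = "b",
    flavor: str = "student",
) -> StatResult:
    """Two-sided two-sample t-test on alr-transformed abundances.

    ``flavor="student"`` uses the pooled-variance test; ``"welch"`` relaxes
    the equal-variance assumption.  Requires >= 2 values per group and not
    both within-group variances zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            f"{feature or 'feature'}: need >= 2 replicates per group "
            f"(got {a.size} and {b.size})"
        )
    if flavor not in {"student", "welch"}:
        raise ValidationError(f"unknown t-test flavor {flavor!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            raise ValidationError(
                f"{feature or 'feature'}: both groups have zero variance"
            )
    else:
        t, p = sps.ttest_ind(a, b, equal_var=(flavor == "student"))
        t, p = float(t), float(p)
    return StatResult(
        feature, group_a, group_b, int(a.size), int(b.size),
        float(a.mean()), float(b.mean()), t, p, significance_tier(p),
    )


def feature_alr_values(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    value_col: str = "fraction",
    delta_factor: float = 0.65,
) -> pd.DataFrame:
    """2-part alr values per feature, with per-feature zero replacement.

    *table* is long (one row per sample x replicate x feature with a fraction
    in [0, 1]); missing features are simply absent rows, never zeros.  Exact
    zeros (and ones) are replaced via :func:`zero_replace` on the 2-part
    composition (x, 1-x) with the feature's default delta.
    """
    df = table.copy()
    df["feature"] = df[list(feature_cols)].astype(str).agg("|".join, axis=1)
    out_rows = []
    for feat, sub in df.groupby("feature", sort=False):
        x = sub[value_col].to_numpy(dtype=float)
        needs = (x == 0) | (x == 1)
        if needs.any():
            interior = np.concatenate([x[~needs], 1 - x[~needs]])
            delta = default_delta(interior, delta_factor) if interior.size else 1e-4
            logger.info("zero replacement for %s with delta %.3g", feat, delta)
            x = x.copy()
            for idx in np.nonzero(needs)[0]:
                x[idx] = zero_replace(np.array([x[idx], 1 - x[idx]]), delta)[0]
        vals = np.log2(x / (1 - x))
        chunk = sub[["sample_group", "replicate"]].copy()
        chunk["feature"] = feat
        chunk["alr"] = vals
        out_rows.append(chunk)
    return pd.concat(out_rows, ignore_index=True)


def compare_groups(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    feature_cols: Sequence[str] = ("region_id", "modifications"),
    value_col: str = "fraction",
    flavor: str = "student",
    delta_factor: float = 0.65,
) -> pd.DataFrame:
    """Per-feature t-test report between two groups on the alr scale.

    Features with fewer than two replicates in either group are skipped with
    a logged reason (mirroring forms undetected in low-yield samples).  The
    report carries the uncorrected p-value and tier plus Benjamini-Hochberg
    q-values in a separate column.
    """
    alr = feature_alr_values(table, feature_cols, value_col, delta_factor)
    results: list[StatResult] = []
    for feat, sub in alr.groupby("feature", sort=False):
        va = sub.loc[sub["sample_group"] == group_a, "alr"].to_numpy()
        vb = sub.loc[sub["sample_group"] == group_b, "alr"].to_numpy()
        try:
            results.append(
                group_ttest(va, vb, feat, group_a, group_b, flavor=flavor)
            )
        except ValidationError as err:
            logger.info("skipping %s: %s", feat, err)
    if not results:
        raise ValidationError(
            f"no feature testable between {group_a} and {group_b}"
        )
    report = pd.DataFrame([r.__dict__ for r in results])
    report["q_value"] = multipletests(report["p_value"], method="fdr_bh")[1]
    return report


# ---------------------------------------------------------------------------
# pivot coordinates


def pivot_coordinates(
    composition: Sequence[float],
    pivot_order: Sequence[int] | None = None,
) -> np.ndarray:
    """Pivot (ilr) coordinates of a strictly positive composition.

    With parts taken in *pivot_order* (default: input order), coordinate j is

        z_j = sqrt((D-j)/(D-j+1)) * ln( x_(j) / gmean(x_(j+1)..x_(D)) )

    for j = 1..D-1 (natural log).  Euclidean distance between coordinate
    vectors equals the Aitchison distance, independent of the pivot order.
    """
    x = np.asarray(composition, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("composition must be a vector with >= 2 parts")
    if (x <= 0).any():
        raise ValidationError(
            "non-positive part; apply zero_replace before pivot_coordinates"
        )
    if pivot_order is not None:
        order = list(pivot_order)
        if sorted(order) != list(range(x.size)):
            raise ValidationError("pivot_order must be a permutation of the parts")
        x = x[order]
    D = x.size
    logx = np.log(x)
    # mean of log of the trailing block, computed right-to-left
    tail_mean = np.empty(D)
    tail_mean[-1] = logx[-1]
    for j in range(D - 2, -1, -1):
        tail_mean[j] = (logx[j] + (D - 1 - j) * tail_mean[j + 1]) / (D - j)
    j = np.arange(1, D)
    coef = np.sqrt((D - j) / (D - j + 1.0))
    return coef * (logx[:-1] - tail_mean[1:])


# ---------------------------------------------------------------------------
# hierarchical clustering (UPGMA)


@dataclass(frozen=True)
class ClusterResult:
    """Average-linkage tree over sample PTM profiles."""

    labels: tuple[str, ...]
    linkage: np.ndarray        # scipy-style (n-1, 4) merge table
    leaf_order: tuple[int, ...]
    coordinates_used: np.ndarray

    def newick(self) -> str:
        return linkage_to_newick(self.linkage, self.labels)

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat assignment of labels to *n_clusters* top clusters."""
        flat = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def hclust_average(
    profiles: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
) -> ClusterResult:
    """UPGMA (unweighted average linkage) on Euclidean row distances.

    The inter-cluster distance is the mean over all cross pairs of the
    original row distances.  Ties are broken deterministically by the lowest
    (i, j) cluster-index pair.  Merge heights are non-decreasing (average
    linkage is reducible, hence monotone).
    """
    if isinstance(profiles, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in profiles.index]
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need >= 2 rows to cluster")
    if np.isnan(X).any():
        raise ValidationError(
            "missing values in profile matrix; drop incomplete features first"
        )
    if len(labels) != X.shape[0]:
        raise ValidationError("label count does not match row count")

    n = X.shape[0]
    d = squareform(pdist(X))
    dists = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(sizes) > 1:
        (i, j) = min(dists, key=lambda p: (dists[p], p))
        h = dists.pop((i, j))
        ni, nj = sizes.pop(i), sizes.pop(j)
        for k in list(sizes):
            dik = dists.pop((min(i, k), max(i, k)))
            djk = dists.pop((min(j, k), max(j, k)))
            dists[(k, next_id)] = (ni * dik + nj * djk) / (ni + nj)
        sizes[next_id] = ni + nj
        merges.append((i, j, h, ni + nj))
        next_id += 1
    Z = np.array(merges, dtype=float)
    leaf_order = tuple(int(i) for i in sch.leaves_list(Z))
    return ClusterResult(tuple(str(l) for l in labels), Z, leaf_order, X)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage table as an ultrametric Newick string.

    Node heights are merge height / 2, so leaf-to-leaf path length equals the
    average-linkage distance between their clusters.
    """
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: str(labels[i]) for i in range(n)}
    for k, (i, j, h, _) in enumerate(Z):
        i, j, hh = int(i), int(j), float(h) / 2.0
        node[n + k] = (
            f"({node[i]}:{hh - height[i]:.10g},{node[j]}:{hh - height[j]:.10g})"
        )
        height[n + k] = hh
    return node[n + len(Z) - 1] + ";"


# ---------------------------------------------------------------------------
# profile matrices for clustering


def build_profile_matrix(
    table: pd.DataFrame,
    scope: str = "all-peptides",
    regions: Sequence[str] | None = None,
    unit: str = "group-mean",
    feature_cols: Sequence[str] = ("modifications",),
    value_col: str = "fraction",
    delta_factor: float = 0.65,
) -> tuple[pd.DataFrame | dict[str, pd.DataFrame], dict[str, list[str]]]:
    """Pivot-coordinate matrices of sample PTM profiles for clustering.

    *table* is a long composition (or site-mark) table with a ``region_id``
    column.  For each region, unit profiles are formed (group means of the
    replicate fractions by default, after which each profile is re-closed),
    features absent in any clustered unit are dropped matrix-wide (returned
    in the drop log), remaining zeros are multiplicatively replaced, and the
    profiles are mapped to pivot coordinates.

    ``scope="per-peptide"`` returns ``{region_id: matrix}``;
    ``"all-peptides"`` concatenates the per-region coordinates column-wise
    (rows = clustered units).
    """
    if scope not in {"per-peptide", "all-peptides"}:
        raise ValidationError(f"unknown scope {scope!r}")
    if unit not in {"group-mean", "replicate"}:
        raise ValidationError(f"unknown clustering unit {unit!r}")
    region_ids = list(regions) if regions is not None else sorted(
        pd.unique(table["region_id"])
    )
    unit_cols = ["sample_group"] if unit == "group-mean" else [
        "sample_group", "replicate"
    ]
    matrices: dict[str, pd.DataFrame] = {}
    dropped: dict[str, list[str]] = {}
    for region_id in region_ids:
        sub = table.loc[table["region_id"] == region_id].copy()
        if sub.empty:
            raise ValidationError(f"no data for region {region_id}")
        sub["feature"] = sub[list(feature_cols)].astype(str).agg("|".join, axis=1)
        wide = sub.pivot_table(
            index=unit_cols, columns="feature", values=value_col, aggfunc="mean"
        )
        incomplete = [c for c in wide.columns if wide[c].isna().any()]
        if incomplete:
            logger.info(
                "dropping %d feature(s) of %s missing in some unit: %s",
                len(incomplete), region_id, incomplete,
            )
        dropped[region_id] = incomplete
        wide = wide.drop(columns=incomplete)
        if wide.shape[1] < 2:
            raise ValidationError(
                f"{region_id}: fewer than 2 features survive the missingness rule"
            )
        # re-close after averaging/drops, then replace residual zeros
        M = wide.to_numpy(dtype=float)
        M = M / M.sum(axis=1, keepdims=True)
        if (M == 0).any():
            delta = default_delta(M[M > 0].ravel(), delta_factor)
            M = np.vstack([zero_replace(row, delta) for row in M])
        coords = np.vstack([pivot_coordinates(row) for row in M])
        cols = [f"{region_id}|z{j + 1}" for j in range(coords.shape[1])]
        if unit == "group-mean":
            idx = wide.index
        else:
            idx = pd.Index(
                [f"{g}#{r}" for g, r in wide.index], name="unit"
            )
        matrices[region_id] = pd.DataFrame(coords, index=idx, columns=cols)
    if scope == "per-peptide":
        return matrices, dropped
    joined = pd.concat(matrices.values(), axis=1)
    if joined.isna().any().any():
        bad = joined.index[joined.isna().any(axis=1)].tolist()
        raise ValidationError(
            f"units missing entire regions cannot be clustered jointly: {bad}"
        )
    return joined, dropped
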