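"""Replicate-level statistics: permutation tests, effect sizes, power, density.

The exchangeable unit throughout is the biological replicate (well), not
the individual synapse: each comparison reduces synapse-level measurements
to per-replicate means first, then tests untreated against treated wells
with a two-tailed permutation test on the mean difference, Cohen's d with
a BCa bootstrap confidence interval, and two-sample t-test power from the
noncentral t distribution.  Per-cluster correlation structure is summarized
by replicate-wise Pearson matrices averaged element-wise, with weak entries
masked; dendritic synapse density is reported per 100 um of skeletonized
dendrite at the acquisition pixel size.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.special import ndtri
from scipy.stats import nct
from scipy.stats import t as t_dist
from skimage.morphology import skeletonize
from statsmodels.stats.multitest import multipletests

from .subtype_clustering import ClusterAssignment, intensity_column
from .synthetic_data import SYNAPTIC_TARGETS

logger = logging.getLogger(__name__)

DEFAULT_N_SHUFFLES = 5000
DEFAULT_N_BOOT = 5000
DEFAULT_MASK_BOUND = 0.4
DEFAULT_PIXEL_SIZE_UM = 0.187


# --------------------------------------------------------------------------
# Permutation t test
# --------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    ci_low: float
    ci_high: float
    n_shuffles: int
    exact: bool


def permutation_t_test(
    a,
    b,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    ci_level: float = 0.95,
) -> PermutationResult:
    """Two-tailed permutation test on the difference of group means.

    The null distribution reshuffles group labels over the pooled values.
    When the number of distinct relabelings C(n1+n2, n1) does not exceed
    ``n_shuffles`` the test enumerates all of them exactly (the identity
    relabeling included); otherwise it draws ``n_shuffles`` random
    relabelings and applies the (count+1)/(n+1) convention so p is never 0.
    The reported CI on the mean difference is a percentile bootstrap
    (``n_shuffles`` resamples of each group).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicate values")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    if np.ptp(pooled) == 0:
        logger.warning("all values identical across both groups; p = 1")
        return PermutationResult(observed, 1.0, 0.0, 0.0, 0, True)
    n1, n = a.size, pooled.size
    tol = 1e-12 * max(1.0, abs(observed))
    n_comb = math.comb(n, n1)
    if n_comb <= n_shuffles:
        total_sum = pooled.sum()
        count = 0
        for idx in itertools.combinations(range(n), n1):
            sa = pooled[list(idx)].sum()
            diff = sa / n1 - (total_sum - sa) / (n - n1)
            if abs(diff) >= abs(observed) - tol:
                count += 1
        p = count / n_comb
        exact = True
        n_used = n_comb
    else:
        count = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(pooled)
            diff = perm[:n1].mean() - perm[n1:].mean()
            if abs(diff) >= abs(observed) - tol:
                count += 1
        p = (count + 1) / (n_shuffles + 1)
        exact = False
        n_used = n_shuffles
    boot = np.empty(n_shuffles)
    for i in range(n_shuffles):
        boot[i] = (
            rng.choice(a, size=a.size, replace=True).mean()
            - rng.choice(b, size=b.size, replace=True).mean()
        )
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(boot, [100 * alpha, 100 * (1 - alpha)])
    return PermutationResult(observed, float(p), float(lo), float(hi), n_used, exact)


# --------------------------------------------------------------------------
# Effect size and bootstrap intervals
# --------------------------------------------------------------------------


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled (Bessel-corrected) standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = a.size, b.size
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def _bca_interval(theta_hat, boot, jack, level):
    boot = np.asarray(boot, dtype=float)
    if np.ptp(boot) == 0:
        logger.warning("degenerate bootstrap distribution; returning point interval")
        v = float(boot[0])
        return v, v
    prop = np.mean(boot < theta_hat)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), 1 - 1.0 / (len(boot) + 1))
    z0 = ndtri(prop)
    jack = np.asarray(jack, dtype=float)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        z = z0 + ndtri(q)
        adj = z0 + z / (1.0 - a * z)
        out.append(float(np.percentile(boot, 100.0 * _ndtr(adj))))
    return out[0], out[1]


def _ndtr(x: float) -> float:
    from scipy.special import ndtr

    return float(ndtr(x))


def bca_ci(
    values,
    statistic,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for a one-sample statistic.

    Bias correction z0 comes from the fraction of bootstrap replicates
    below the point estimate; acceleration from the jackknife skewness of
    the statistic; the interval endpoints are the correspondingly adjusted
    percentiles of the bootstrap distribution.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    theta_hat = float(statistic(values))
    if np.ptp(values) == 0:
        return theta_hat, theta_hat
    boot = np.array(
        [statistic(rng.choice(values, size=values.size, replace=True))
         for _ in range(n_boot)]
    )
    jack = np.array(
        [statistic(np.delete(values, i)) for i in range(values.size)]
    )
    return _bca_interval(theta_hat, boot, jack, level)


def bca_ci_two_sample(
    a,
    b,
    statistic,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """BCa interval for a two-sample statistic (groups resampled independently).

    The jackknife for the acceleration deletes one observation at a time
    across both groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    theta_hat = float(statistic(a, b))
    boot = np.array(
        [
            statistic(
                rng.choice(a, size=a.size, replace=True),
                rng.choice(b, size=b.size, replace=True),
            )
            for _ in range(n_boot)
        ]
    )
    jack = [statistic(np.delete(a, i), b) for i in range(a.size)]
    jack += [statistic(a, np.delete(b, i)) for i in range(b.size)]
    return _bca_interval(theta_hat, boot, np.array(jack), level)


# --------------------------------------------------------------------------
# Power
# --------------------------------------------------------------------------


def power_t2n(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test with unequal group sizes.

    Uses the noncentral t distribution with noncentrality
    d * sqrt(n1 n2 / (n1 + n2)) and n1 + n2 - 2 degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    df_ = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = t_dist.ppf(1.0 - alpha / 2.0, df_)
    upper = nct.sf(tcrit, df_, ncp)
    lower = nct.cdf(-tcrit, df_, ncp)
    # extreme noncentrality underflows the nct implementation; use its limit
    if np.isnan(upper):
        upper = 1.0 if ncp > tcrit else 0.0
    if np.isnan(lower):
        lower = 1.0 if -ncp > tcrit else 0.0
    return float(upper + lower)


# --------------------------------------------------------------------------
# Correlation structure
# --------------------------------------------------------------------------


@dataclass
class CorrelationSummary:
    cluster_id: int
    targets: list[str]
    per_replicate: dict[int, pd.DataFrame]
    averaged: pd.DataFrame
    masked: pd.DataFrame
    leaf_order: list[str]


def cluster_correlation_matrices(
    table: pd.DataFrame,
    assignment: ClusterAssignment | None = None,
    mask_bound: float = DEFAULT_MASK_BOUND,
    min_synapses: int = 3,
) -> list[CorrelationSummary]:
    """Per-cluster averaged Pearson correlation of per-synapse target levels.

    Within each cluster a correlation matrix over the target intensity
    columns is computed per replicate (replicates contributing fewer than
    ``min_synapses`` synapses are skipped; constant targets yield NA
    entries excluded from the average), matrices are averaged element-wise,
    entries with |r| < ``mask_bound`` are masked to NA (|r| equal to the
    bound is kept), and a hierarchical average-linkage leaf order on
    distance 1 - r of the unmasked average is attached.
    """
    df = table.data if hasattr(table, "data") else table
    if assignment is not None:
        labels = np.asarray(assignment.labels)
        cluster_ids = assignment.cluster_ids
    else:
        labels = np.zeros(len(df), dtype=int)
        cluster_ids = [0]
    targets = []
    cols = []
    for t in SYNAPTIC_TARGETS:
        try:
            cols.append(intensity_column(df, t))
            targets.append(t)
        except KeyError:
            continue
    out = []
    for cid in cluster_ids:
        sel = df[labels == cid]
        per_rep: dict[int, pd.DataFrame] = {}
        mats = []
        for rep, grp in sel.groupby("replicate", sort=True):
            if len(grp) < min_synapses:
                continue
            corr = grp[cols].corr(method="pearson")
            corr.index = corr.columns = targets
            per_rep[rep] = corr
            mats.append(corr.to_numpy())
        if not mats:
            logger.warning("cluster %s has no replicate with >= %d synapses",
                           cid, min_synapses)
            continue
        avg = np.nanmean(np.stack(mats), axis=0)
        np.fill_diagonal(avg, 1.0)
        averaged = pd.DataFrame(avg, index=targets, columns=targets)
        masked = averaged.where(averaged.abs() >= mask_bound)
        filled = np.nan_to_num(avg, nan=0.0)
        dist = 1.0 - (filled + filled.T) / 2.0
        np.fill_diagonal(dist, 0.0)
        order = leaves_list(average(squareform(dist, checks=False)))
        out.append(
            CorrelationSummary(
                cluster_id=int(cid),
                targets=targets,
                per_replicate=per_rep,
                averaged=averaged,
                masked=masked,
                leaf_order=[targets[i] for i in order],
            )
        )
    return out


# --------------------------------------------------------------------------
# Dendritic density
# --------------------------------------------------------------------------

_DIAGONAL_OFFSETS = ((1, 1), (1, -1))
_AXIAL_OFFSETS = ((0, 1), (1, 0))


def dendrite_length_um(
    dendrite_mask: np.ndarray, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> float:
    """Skeletonized dendrite length in micrometers.

    The mask is morphologically skeletonized; length in pixels is the
    skeleton pixel count plus (sqrt(2) - 1) for every purely diagonal link
    (8-adjacent pixel pairs that are not bridged by a common 4-neighbor),
    so straight runs count one pixel per pixel and diagonal runs count
    sqrt(2).  Splitting a field and summing lengths is exact for axial
    seams.
    """
    mask = np.asarray(dendrite_mask, bool)
    if not mask.any():
        raise ValueError("dendrite mask is empty")
    skel = skeletonize(mask)
    n = int(skel.sum())
    if n == 0:
        raise ValueError("skeleton is empty")
    padded = np.pad(skel, 1)

    def neighbor(dr: int, dc: int) -> np.ndarray:
        return padded[1 + dr : padded.shape[0] - 1 + dr,
                      1 + dc : padded.shape[1] - 1 + dc]

    diag = 0
    for dr, dc in _DIAGONAL_OFFSETS:
        pair = skel & neighbor(dr, dc)
        bridged = neighbor(dr, 0) | neighbor(0, dc)
        diag += int((pair & ~bridged).sum())
    length_px = n + (np.sqrt(2.0) - 1.0) * diag
    return float(length_px * pixel_size_um)


def synapse_density(
    counts: dict[str, int] | int,
    dendrite_mask: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> dict[str, float]:
    """Synapses per 100 um of dendrite, overall or per class/cluster.

    ``counts`` is either a single count or a mapping label -> count;
    the returned dict always includes ``length_um``.
    """
    length = dendrite_length_um(dendrite_mask, pixel_size_um)
    if isinstance(counts, (int, np.integer)):
        counts = {"all": int(counts)}
    out = {"length_um": length}
    for key, cnt in counts.items():
        out[f"density_{key}"] = 100.0 * cnt / length
    return out


# --------------------------------------------------------------------------
# Condition comparisons
# --------------------------------------------------------------------------


@dataclass
class GroupComparison:
    target: str
    scope: str
    n_untreated: int
    n_treated: int
    untreated_means: tuple[float, ...]
    treated_means: tuple[float, ...]
    observed_difference: float
    p_value: float
    diff_ci_low: float
    diff_ci_high: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    power: float


def _battery(
    target: str, scope: str, ut: np.ndarray, tt: np.ndarray,
    n_shuffles: int, n_boot: int, seed: int,
) -> GroupComparison:
    perm = permutation_t_test(ut, tt, n_shuffles=n_shuffles, seed=seed)
    try:
        d = cohens_d(ut, tt)
        d_lo, d_hi = bca_ci_two_sample(
            ut, tt, cohens_d, n_boot=n_boot, seed=seed + 1
        )
        power = power_t2n(d, ut.size, tt.size)
    except ValueError:
        d, d_lo, d_hi, power = 0.0, 0.0, 0.0, np.nan
    return GroupComparison(
        target=target,
        scope=scope,
        n_untreated=ut.size,
        n_treated=tt.size,
        untreated_means=tuple(np.round(ut, 10)),
        treated_means=tuple(np.round(tt, 10)),
        observed_difference=perm.observed,
        p_value=perm.p_value,
        diff_ci_low=perm.ci_low,
        diff_ci_high=perm.ci_high,
        cohens_d=d,
        d_ci_low=d_lo,
        d_ci_high=d_hi,
        power=power,
    )


def _replicate_means(
    df: pd.DataFrame, col: str, positive_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    sel = df
    if positive_only:
        sel = sel[sel[col] > 0]
    means = sel.groupby(["treatment", "replicate"])[col].mean()
    ut = means.get("untreated", pd.Series(dtype=float)).to_numpy()
    tt = means.get("treated", pd.Series(dtype=float)).to_numpy()
    return ut, tt


def compare_conditions(
    table: pd.DataFrame,
    assignment: ClusterAssignment | None = None,
    densities: pd.DataFrame | None = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Untreated-vs-treated battery per target and scope.

    Scopes are all excitatory synapses, all inhibitory synapses, and (when
    a cluster assignment is given) each cluster.  Synapse-level normalized
    integrated intensities are reduced to per-replicate means, which are
    the exchangeable units of the permutation test; Cohen's d with BCa CI
    and noncentral-t power complete each row.  When ``densities`` is given
    (columns replicate, treatment, cluster, density) the same battery runs
    on per-replicate synapse density per cluster.  A Benjamini-Hochberg
    adjusted p column is appended for information; inference follows the
    raw permutation p values.
    """
    df = table.data if hasattr(table, "data") else table
    scopes: list[tuple[str, np.ndarray]] = [
        ("excitatory", (df["class"] == "excitatory").to_numpy()),
        ("inhibitory", (df["class"] == "inhibitory").to_numpy()),
    ]
    if assignment is not None:
        for cid in assignment.cluster_ids:
            scopes.append((f"cluster_{cid}", assignment.labels == cid))
    rows = []
    comparison_seed = seed
    for target in SYNAPTIC_TARGETS:
        try:
            col = intensity_column(df, target)
        except KeyError:
            continue
        for scope_name, mask in scopes:
            sub = df[mask]
            ut, tt = _replicate_means(sub, col, positive_only)
            comparison_seed += 2
            if ut.size < 2 or tt.size < 2:
                logger.warning("scope %s for %s has <2 replicates per condition; skipped",
                               scope_name, target)
                continue
            rows.append(_battery(target, scope_name, ut, tt,
                                 n_shuffles, n_boot, comparison_seed))
    if densities is not None:
        for cid, grp in densities.groupby("cluster", sort=True):
            piv = grp.groupby(["treatment", "replicate"])["density"].mean()
            ut = piv.get("untreated", pd.Series(dtype=float)).to_numpy()
            tt = piv.get("treated", pd.Series(dtype=float)).to_numpy()
            comparison_seed += 2
            if ut.size < 2 or tt.size < 2:
                logger.warning("density scope cluster %s skipped (<2 replicates)", cid)
                continue
            ut_rel = ut / ut.mean() if ut.mean() != 0 else ut
            tt_rel = tt / ut.mean() if ut.mean() != 0 else tt
            rows.append(_battery("synapse_density", f"cluster_{cid}",
                                 ut_rel, tt_rel, n_shuffles, n_boot, comparison_seed))
    columns = [f.name for f in dataclasses.fields(GroupComparison)] + ["p_bh"]
    if not rows:
        return pd.DataFrame(columns=columns)
    result = pd.DataFrame([r.__dict__ for r in rows])
    result["p_bh"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result[columns]
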