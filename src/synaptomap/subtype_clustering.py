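"""Synapse subtype discovery: subsample, prune, scale, embed, cluster.

Replicate-balanced subsampling keeps each biological replicate's
contribution equal; correlated features are pruned by the caret-style
findCorrelation rule; columns are centred and scaled; a 2D UMAP embedding
is fitted on the subsample and can transform held-out rows; and density
clusters are extracted with HDBSCAN (minimum cluster size 100, low-density
rows flagged as noise and excluded from profiles).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .feature_extraction import FeatureTable, feature_name
from .synthetic_data import ANCHOR_TARGET, SYNAPTIC_TARGETS

logger = logging.getLogger(__name__)

DEFAULT_SUBSAMPLE_QUOTA = 2000
DEFAULT_CORRELATION_CUTOFF = 0.90
DEFAULT_MIN_CLUSTER_SIZE = 100
DEFAULT_N_NEIGHBORS = 15
DEFAULT_MIN_DIST = 0.1


def _as_df(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    return table.data if isinstance(table, FeatureTable) else table


# --------------------------------------------------------------------------
# Subsampling
# --------------------------------------------------------------------------


def subsample_replicates(
    table: FeatureTable | pd.DataFrame,
    quota: int = DEFAULT_SUBSAMPLE_QUOTA,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform per-replicate subsample so each replicate contributes equally.

    At most ``quota`` rows are drawn without replacement from each
    replicate; replicates with fewer rows contribute everything they have
    (with a warning, since they then carry less weight than intended).
    """
    df = _as_df(table)
    rng = np.random.default_rng(seed)
    picks = []
    for rep, grp in df.groupby("replicate", sort=True):
        if len(grp) <= quota:
            if len(grp) < quota:
                logger.warning(
                    "replicate %s has only %d synapses (< quota %d); keeping all",
                    rep, len(grp), quota,
                )
            picks.append(grp.index.to_numpy())
        else:
            picks.append(
                np.sort(rng.choice(grp.index.to_numpy(), size=quota, replace=False))
            )
    return df.loc[np.concatenate(picks)].reset_index(drop=True)


# --------------------------------------------------------------------------
# Feature pruning
# --------------------------------------------------------------------------


def prune_correlated_features(
    df: pd.DataFrame, cutoff: float = DEFAULT_CORRELATION_CUTOFF
) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop one member of every feature pair with |r| > cutoff.

    Constant (zero-variance) columns are dropped first.  Then, repeatedly,
    the most-correlated remaining pair is found and the member with the
    larger mean absolute correlation to all other remaining columns is
    dropped (ties toward the later column), until no pair exceeds the
    cutoff.  Deterministic for a given column order.
    """
    numeric = df.select_dtypes(include=[np.number])
    dropped: list[str] = []
    constant = [c for c in numeric.columns if numeric[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("dropping %d constant columns before correlation pruning",
                       len(constant))
        dropped.extend(constant)
    cols = [c for c in numeric.columns if c not in constant]
    while len(cols) > 1:
        corr = numeric[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
        if not corr[i, j] > cutoff:
            break
        mean_i = np.nanmean(np.delete(corr[i], i))
        mean_j = np.nanmean(np.delete(corr[j], j))
        victim = cols[j] if mean_j >= mean_i else cols[i]
        dropped.append(victim)
        cols.remove(victim)
    return df[[c for c in df.columns if c not in dropped]], dropped


# --------------------------------------------------------------------------
# Scaling
# --------------------------------------------------------------------------


@dataclass
class ScalingParams:
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray


def center_scale(df: pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Centre and scale every numeric column to mean 0, sd 1 (sample sd).

    The fitted means/sds are returned so held-out rows can be transformed
    identically.  A zero-variance column is an error; it should have been
    pruned beforehand.
    """
    numeric = df.select_dtypes(include=[np.number])
    means = numeric.mean().to_numpy()
    sds = numeric.std(ddof=1).to_numpy()
    if np.any(sds == 0) or np.any(~np.isfinite(sds)):
        bad = numeric.columns[(sds == 0) | ~np.isfinite(sds)].tolist()
        raise ValueError(f"zero-variance columns cannot be scaled: {bad}")
    out = df.copy()
    out[numeric.columns] = (numeric - means) / sds
    return out, ScalingParams(list(numeric.columns), means, sds)


def apply_scaling(df: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    missing = [c for c in params.columns if c not in df.columns]
    if missing:
        raise KeyError(f"rows lack fitted columns: {missing[:5]}")
    out = df.copy()
    out[params.columns] = (df[params.columns] - params.means) / params.sds
    return out


# --------------------------------------------------------------------------
# Embedding
# --------------------------------------------------------------------------


@dataclass
class EmbeddingModel:
    """Fitted 2D manifold projection plus the column order it expects."""

    umap: object
    columns: list[str]
    seed: int

    @property
    def training_coordinates(self) -> np.ndarray:
        return np.asarray(self.umap.embedding_)


def fit_embedding(
    df: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
) -> tuple[EmbeddingModel, np.ndarray]:
    """Fit a 2D UMAP embedding on scaled feature rows.

    A fixed ``random_state`` makes the layout reproducible (this also pins
    UMAP to its single-threaded path).  Returns the model and the training
    coordinates.
    """
    numeric = df.select_dtypes(include=[np.number])
    if len(numeric) < 10:
        raise ValueError(f"need at least 10 rows to embed, got {len(numeric)}")
    import umap  # deferred: numba compilation makes this import expensive

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="euclidean",
            random_state=seed,
        )
        coords = model.fit_transform(numeric.to_numpy(dtype=float))
    return EmbeddingModel(model, list(numeric.columns), seed), np.asarray(coords)


def transform_embedding(model: EmbeddingModel, df: pd.DataFrame) -> np.ndarray:
    """Project held-out (already scaled) rows with a fitted embedding."""
    numeric = df.select_dtypes(include=[np.number])
    if list(numeric.columns) != model.columns:
        raise KeyError("column set/order does not match the fitted embedding")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(model.umap.transform(numeric.to_numpy(dtype=float)))


# --------------------------------------------------------------------------
# Density clustering
# --------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    """Per-row cluster ids 1..K (−1 = noise), renumbered by descending size."""

    labels: np.ndarray
    min_cluster_size: int

    @property
    def k(self) -> int:
        return int(len(self.cluster_ids))

    @property
    def cluster_ids(self) -> list[int]:
        return sorted({int(l) for l in self.labels if l > 0})

    @property
    def noise_mask(self) -> np.ndarray:
        return self.labels < 0

    def size(self, cluster_id: int) -> int:
        return int((self.labels == cluster_id).sum())


def cluster_embedding(
    coords: np.ndarray, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> ClusterAssignment:
    """HDBSCAN on the 2D embedding; noise points get label −1.

    Clusters are renumbered 1..K by descending size for stable reporting.
    Every reported cluster has at least ``min_cluster_size`` members.
    """
    coords = np.asarray(coords, dtype=float)
    raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(coords)
    labels = np.full(len(raw), -1, dtype=int)
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    # stable renumbering: by descending size, ties by original id
    order = sorted(zip(ids, counts), key=lambda t: (-t[1], t[0]))
    for new_id, (old_id, _) in enumerate(order, start=1):
        labels[raw == old_id] = new_id
    return ClusterAssignment(labels=labels, min_cluster_size=min_cluster_size)


# --------------------------------------------------------------------------
# Cluster profiles
# --------------------------------------------------------------------------


def intensity_column(table: pd.DataFrame, target: str) -> str:
    """Canonical integrated-intensity column of a target.

    Prefers the anchor-region measurement; falls back to the target's own
    child-region measurement when the anchor-region column was not kept
    (the published reduced feature list omits a few anchor-region pairs).
    """
    primary = feature_name("IntegratedIntensity", ANCHOR_TARGET, target)
    if primary in table.columns:
        return primary
    fallback = feature_name("IntegratedIntensity", target, target)
    if fallback in table.columns:
        return fallback
    raise KeyError(f"no integrated-intensity column for {target}")


def cluster_profiles(
    table: FeatureTable | pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Mean relative intensity and detectable fraction per target per cluster.

    Noise rows are excluded.  Also reports each cluster's share of
    excitatory and inhibitory synapses.  Rows: clusters; columns:
    ``mean_<target>``, ``detectable_<target>`` (fraction of synapses with
    intensity > 0), size, and class shares.
    """
    df = _as_df(table)
    if len(df) != len(assignment.labels):
        raise ValueError("assignment is not aligned to the table rows")
    records = []
    for cid in assignment.cluster_ids:
        sel = df[assignment.labels == cid]
        if sel.empty:
            logger.warning("cluster %d is empty; skipped", cid)
            continue
        rec: dict = {"cluster": cid, "size": len(sel)}
        for target in SYNAPTIC_TARGETS:
            try:
                col = intensity_column(df, target)
            except KeyError:
                continue
            vals = sel[col]
            rec[f"mean_{target}"] = float(vals.mean(skipna=True))
            rec[f"detectable_{target}"] = float((vals > 0).mean())
        if "class" in sel.columns:
            rec["share_excitatory"] = float((sel["class"] == "excitatory").mean())
            rec["share_inhibitory"] = float((sel["class"] == "inhibitory").mean())
        records.append(rec)
    return pd.DataFrame(records)
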