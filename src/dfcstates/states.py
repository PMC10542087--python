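"""Recurring connectivity states and their temporal statistics.

All subjects' windowed connectivity matrices are pooled (as upper-triangle
Fisher-Z vectors) and partitioned with K-means into K recurring whole-brain
states.  Per subject we then compute the temporal signature of state use:
mean dwell time (MDT, mean length of maximal runs in a state, window units),
fractional windows (occupancy share), and the number of transitions — and
contrast them between groups with a covariate-adjusted linear model.

Clustering conventions (pinned for reproducibility): squared-Euclidean
distance on upper-triangle Z vectors, k-means++ initialisation, best of
``n_restarts`` by inertia, states renumbered by descending pooled occupancy
so "state 1" is always the most occupied state.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._glm import encode_design
from .windows import WindowedFC, upper_vec, vec_to_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "StateModel",
    "fit_states",
    "select_k",
    "temporal_metrics",
    "mdt_to_seconds",
    "compare_temporal",
    "state_mean_fc",
    "state_mean_fc_cohort",
]

ELBOW_TOL = 0.03  # minimum second difference of log-inertia to count as an elbow


@dataclasses.dataclass
class StateModel:
    """Fitted connectivity-state model.

    ``centroids`` holds K upper-triangle Fisher-Z vectors (row-major upper
    triangle order); ``labels`` maps subject_id to a length-W vector of
    1-based state labels ordered by window; states are numbered by
    descending pooled occupancy.
    """

    k: int
    centroids: np.ndarray
    labels: dict
    inertia: float
    seed: int
    n_regions: int
    validity_curve: dict | None = None

    def centroid_matrix(self, state: int) -> np.ndarray:
        """State centroid as a symmetric N x N Fisher-Z matrix (1-based state)."""
        return vec_to_matrix(self.centroids[state - 1], self.n_regions)

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([self.labels[s] for s in self.labels])


def _pool(wfcs: Sequence[WindowedFC]) -> tuple:
    vecs = np.concatenate([upper_vec(w.z) for w in wfcs], axis=0)
    slices, pos = {}, 0
    for w in wfcs:
        slices[w.subject_id] = slice(pos, pos + w.n_windows)
        pos += w.n_windows
    return vecs, slices


def _kmeans(vecs: np.ndarray, k: int, n_restarts: int, seed: int) -> KMeans:
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=int(seed) % (2**32 - 1),
        algorithm="lloyd",
    )
    km.fit(vecs.astype(np.float32, copy=False))
    return km


def fit_states(
    wfcs: Sequence[WindowedFC],
    k: int,
    n_restarts: int = 50,
    seed: int = 0,
) -> StateModel:
    """K-means over all subjects' window vectors; deterministic given seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    vecs, slices = _pool(wfcs)
    if vecs.shape[0] < k:
        raise ValueError(f"{vecs.shape[0]} pooled windows < k={k}")
    km = _kmeans(vecs, k, n_restarts, seed)
    raw = km.labels_

    # renumber by descending pooled occupancy (ties: original cluster index)
    counts = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -counts))
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(1, k + 1)
    labels_1b = remap[raw]

    # recompute centroids as exact member means in float64
    centroids = np.empty((k, vecs.shape[1]))
    for s in range(1, k + 1):
        centroids[s - 1] = vecs[labels_1b == s].mean(axis=0)

    labels = {sid: labels_1b[sl].copy() for sid, sl in slices.items()}
    n_regions = wfcs[0].n_regions
    return StateModel(
        k=k,
        centroids=centroids,
        labels=labels,
        inertia=float(km.inertia_),
        seed=seed,
        n_regions=n_regions,
    )


def select_k(
    wfcs: Sequence[WindowedFC],
    k_range: Sequence[int] = range(2, 9),
    criterion: str = "elbow",
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple:
    """Sweep K and pick the best by the chosen criterion.

    ``elbow`` (default): K with the maximal second difference of
    log-inertia; if no second difference exceeds ``ELBOW_TOL`` the curve is
    considered flat, the smallest K is returned and the flag is set.
    ``silhouette``: K maximising the mean silhouette width (computed on a
    seeded subsample of at most 2000 windows for tractability).

    Returns ``(k_star, validity_curve, flat_flag)`` where validity_curve
    maps K -> criterion value (inertia for elbow, silhouette width
    otherwise) over the full sweep.
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 3 and criterion == "elbow":
        raise ValueError("elbow criterion needs at least 3 candidate K values")
    vecs, _ = _pool(wfcs)
    if ks[0] < 2 or ks[-1] >= vecs.shape[0]:
        raise ValueError("k_range must lie within [2, pooled window count)")

    if criterion == "elbow":
        inertia = {}
        for k in ks:
            inertia[k] = float(_kmeans(vecs, k, n_restarts, seed).inertia_)
        li = np.log([inertia[k] for k in ks])
        d2 = li[:-2] - 2 * li[1:-1] + li[2:]  # second difference at interior K
        if d2.max() < ELBOW_TOL:
            logger.warning("no elbow above tolerance %.3g; returning smallest K", ELBOW_TOL)
            return ks[0], inertia, True
        return ks[1 + int(np.argmax(d2))], inertia, False

    if criterion == "silhouette":
        rng = np.random.default_rng(seed)
        sub = vecs
        if vecs.shape[0] > 2000:
            sub = vecs[rng.choice(vecs.shape[0], 2000, replace=False)]
        curve = {}
        for k in ks:
            km = _kmeans(vecs, k, n_restarts, seed)
            curve[k] = float(
                silhouette_score(sub.astype(np.float32), km.predict(sub.astype(np.float32)))
            )
        best = max(curve, key=curve.get)
        return best, curve, False

    raise ValueError(f"unknown criterion '{criterion}'")


# ---------------------------------------------------------------------------
# Temporal statistics
# ---------------------------------------------------------------------------

def _runs(seq: np.ndarray) -> tuple:
    """Maximal constant runs: (state per run, length per run)."""
    seq = np.asarray(seq)
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [seq.size]))
    return seq[starts], ends - starts


def temporal_metrics(labels: Mapping[str, np.ndarray], k: int) -> pd.DataFrame:
    """Per-subject MDT, fractional windows and transition count.

    MDT for a never-visited state is 0 (zero-inflated definition) and the
    subject is retained — dropping non-visitors would bias group contrasts
    toward frequent visitors.
    """
    rows = []
    for sid, seq in labels.items():
        seq = np.asarray(seq)
        if seq.size == 0:
            raise ValueError(f"empty label sequence for subject {sid}")
        if seq.min() < 1 or seq.max() > k:
            raise ValueError(f"labels for {sid} outside 1..{k}")
        states, lengths = _runs(seq)
        row = {"subject_id": sid, "n_transitions": int(states.size - 1)}
        for s in range(1, k + 1):
            mask = states == s
            row[f"mdt_{s}"] = float(lengths[mask].mean()) if mask.any() else 0.0
            row[f"frac_{s}"] = float((seq == s).sum() / seq.size)
        rows.append(row)
    return pd.DataFrame(rows)


def mdt_to_seconds(mdt_windows, step: int, tr_seconds: float):
    """Convert MDT from window units to seconds (x step x TR)."""
    return np.asarray(mdt_windows, float) * step * tr_seconds


def compare_temporal(
    metrics: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "education_years"),
    metric_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group contrast of each temporal metric via ``metric ~ group + covariates``.

    Reports the t statistic and two-sided p of the group coefficient
    (patient coded 1, so t > 0 means patient > control), the raw group
    means, and means adjusted to the grand covariate means.  With no
    covariates the t equals the pooled-variance two-sample t exactly.
    """
    merged = metrics.merge(meta, on="subject_id", validate="one_to_one")
    n_a = (merged["group"] == "patient").sum()
    n_b = (merged["group"] == "control").sum()
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    x, names = encode_design(merged, covariates)
    gi = names.index("group")
    if metric_columns is None:
        metric_columns = [
            c for c in metrics.columns
            if c != "subject_id" and pd.api.types.is_numeric_dtype(metrics[c])
        ]
    cov_means = x.mean(axis=0)
    rows = []
    for col in metric_columns:
        y = merged[col].to_numpy(float)
        fit = sm.OLS(y, x).fit()
        t, p = fit.tvalues[gi], fit.pvalues[gi]
        base = cov_means.copy()
        base[gi] = 1.0
        adj_pat = float(base @ fit.params)
        base[gi] = 0.0
        adj_ctl = float(base @ fit.params)
        rows.append(
            {
                "metric": col,
                "t": float(t),
                "p": float(p),
                "mean_patient": float(y[merged["group"] == "patient"].mean()),
                "mean_control": float(y[merged["group"] == "control"].mean()),
                "adj_mean_patient": adj_pat,
                "adj_mean_control": adj_ctl,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-state mean connectivity
# ---------------------------------------------------------------------------

def state_mean_fc(wfc: WindowedFC, labels: np.ndarray, state: int) -> tuple:
    """Mean Z matrix over this subject's windows in ``state``; (matrix|None, visited)."""
    labels = np.asarray(labels)
    if labels.size != wfc.n_windows:
        raise ValueError("labels not aligned to windows")
    mask = labels == state
    if not mask.any():
        return None, False
    return wfc.z[mask].mean(axis=0), True


def state_mean_fc_cohort(
    wfcs: Sequence[WindowedFC], model: StateModel, state: int
) -> dict:
    """Per-subject state-mean matrices for subjects who visit ``state``."""
    out = {}
    for w in wfcs:
        mat, visited = state_mean_fc(w, model.labels[w.subject_id], state)
        if visited:
            out[w.subject_id] = mat
    return out
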