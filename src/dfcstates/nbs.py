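"""Edgewise group comparison with network-based-statistic (NBS) correction.

Per connectivity state, each edge's Fisher-Z value is contrasted between
groups with a covariate-adjusted linear model.  Family-wise control over the
~N^2/2 edge tests uses the network-based statistic: edges with two-sided
p below ``edge_threshold_p`` form a suprathreshold graph whose connected
components are the candidate effects; a permutation null of the *maximal*
component size (in edge count) calibrates a family-wise p per component.

Permutation scheme with covariates: Freedman-Lane — residuals of the
reduced model (covariates only) are permuted and added back to the reduced
fit, then the full model is refit, which preserves the covariate structure
under the null.  The permutation p uses the +1 correction, so p = 0 is
impossible and the smallest attainable value is 1/(n_permutations + 1).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._glm import encode_design, group_t
from .io import NetworkMap
from .windows import upper_vec, vec_to_matrix

logger = logging.getLogger(__name__)

__all__ = ["EdgeStatMap", "NbsResult", "edgewise_glm", "nbs", "summarize_by_network"]


@dataclasses.dataclass
class EdgeStatMap:
    """Edgewise group-contrast statistics for one state.

    ``t_values`` / ``p_values`` are symmetric N x N (diagonal 0 / 1);
    positive t means patient > control.  ``n_per_group`` counts subjects
    who visit the state and therefore enter the model.
    """

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    n_per_group: dict
    state: int | None = None


@dataclasses.dataclass
class NbsResult:
    """Suprathreshold components and their family-wise-corrected p values.

    Each component dict has ``edges`` (list of 0-based (i, j) region index
    pairs), ``size`` (edge count) and ``fwe_p``.
    """

    components: list
    edge_threshold_p: float
    n_permutations: int
    seed: int
    state: int | None = None
    null_max_sizes: np.ndarray | None = None

    @property
    def significant(self):
        return [c for c in self.components if c["fwe_p"] < 0.05]


def _stack_subjects(matrices: Mapping[str, np.ndarray], meta: pd.DataFrame):
    """Align subject matrices with metadata; exclude and report non-visitors."""
    present = [sid for sid in meta["subject_id"] if sid in matrices]
    sub_meta = meta[meta["subject_id"].isin(present)].reset_index(drop=True)
    n_pat = int((sub_meta["group"] == "patient").sum())
    n_ctl = int((sub_meta["group"] == "control").sum())
    excluded = len(meta) - len(present)
    if excluded:
        logger.info("excluding %d subjects who never visit the state", excluded)
    if min(n_pat, n_ctl) < 2:
        raise ValueError(
            f"fewer than 2 visiting subjects in a group "
            f"(patients={n_pat}, controls={n_ctl}); state skipped"
        )
    y = np.stack([upper_vec(np.asarray(matrices[sid])) for sid in sub_meta["subject_id"]])
    n = np.asarray(matrices[present[0]]).shape[0]
    return y, sub_meta, {"patient": n_pat, "control": n_ctl}, n


def edgewise_glm(
    matrices: Mapping[str, np.ndarray],
    meta: pd.DataFrame,
    covariates: Sequence[str] = (),
    state: int | None = None,
) -> EdgeStatMap:
    """Per-edge linear model ``z ~ group + covariates``.

    Subjects absent from ``matrices`` (never visiting the state) are
    excluded; the per-group counts of those entering the model are reported
    in the result.  With no covariates the t equals the pooled two-sample t.
    """
    y, sub_meta, counts, n = _stack_subjects(matrices, meta)
    x, _ = encode_design(sub_meta, covariates)
    t, p, df = group_t(x, y)
    tm = vec_to_matrix(t, n)
    pm = vec_to_matrix(p, n)
    pm[np.eye(n, dtype=bool)] = 1.0
    return EdgeStatMap(t_values=tm, p_values=pm, df=df, n_per_group=counts, state=state)


def _components(p_vec: np.ndarray, thr: float, iu: tuple, n: int) -> list:
    """Connected components of the suprathreshold edge graph, as edge lists."""
    mask = p_vec < thr
    if not mask.any():
        return []
    rows, cols = iu[0][mask], iu[1][mask]
    adj = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    n_comp, node_label = connected_components(adj, directed=False)
    comps: dict[int, list] = {}
    for i, j in zip(rows, cols):
        comps.setdefault(int(node_label[i]), []).append((int(i), int(j)))
    return sorted(comps.values(), key=len, reverse=True)


def nbs(
    matrices: Mapping[str, np.ndarray],
    meta: pd.DataFrame,
    covariates: Sequence[str] = (),
    edge_threshold_p: float = 0.001,
    n_permutations: int = 1000,
    seed: int = 0,
    state: int | None = None,
) -> NbsResult:
    """Network-based statistic: component-level family-wise corrected p values.

    Threshold two-sided edge p at ``edge_threshold_p``; observed components
    are scored by edge count against a permutation null of the maximal
    component size (Freedman-Lane residual permutation, identical
    thresholding).  Zero suprathreshold edges yield an empty component list.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if not 0 < edge_threshold_p < 1:
        raise ValueError("edge_threshold_p must be in (0, 1)")
    y, sub_meta, counts, n = _stack_subjects(matrices, meta)
    x, _ = encode_design(sub_meta, covariates)
    iu = np.triu_indices(n, k=1)

    t_obs, p_obs, df = group_t(x, y)
    observed = _components(p_obs, edge_threshold_p, iu, n)

    # reduced model: everything but the group column
    z = np.delete(x, 1, axis=1)
    beta_red = np.linalg.pinv(z) @ y
    fit_red = z @ beta_red
    res_red = y - fit_red

    rng = np.random.default_rng(seed)
    n_sub = y.shape[0]
    null_max = np.zeros(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n_sub)
        y_perm = fit_red + res_red[perm]
        _, p_perm, _ = group_t(x, y_perm)
        comps = _components(p_perm, edge_threshold_p, iu, n)
        null_max[b] = len(comps[0]) if comps else 0

    components = []
    for edges in observed:
        size = len(edges)
        fwe = (1.0 + np.count_nonzero(null_max >= size)) / (n_permutations + 1.0)
        components.append({"edges": edges, "size": size, "fwe_p": float(fwe)})
    return NbsResult(
        components=components,
        edge_threshold_p=edge_threshold_p,
        n_permutations=n_permutations,
        seed=seed,
        state=state,
        null_max_sizes=null_max,
    )


def summarize_by_network(
    components: list,
    t_values: np.ndarray,
    region_labels: Sequence[str],
    network_map: NetworkMap,
) -> pd.DataFrame:
    """Count suprathreshold edges per network pair, split by effect sign.

    Returns a long-format table (network_a, network_b, n_patient_gt_control,
    n_patient_lt_control); regions missing from the map are pooled under
    ``"unmapped"`` with a logged warning.  Network pairs are unordered
    (network_a <= network_b alphabetically).
    """
    if not components:
        raise ValueError("no components to summarise")
    counts: dict[tuple, list] = {}
    warned = set()
    for comp in components:
        for i, j in comp["edges"]:
            nets = []
            for idx in (i, j):
                lab = region_labels[idx]
                net = network_map.network_of(lab)
                if net is None:
                    net = "unmapped"
                    if lab not in warned:
                        logger.warning("region %s not in network map", lab)
                        warned.add(lab)
                nets.append(net)
            key = tuple(sorted(nets))
            counts.setdefault(key, [0, 0])
            if t_values[i, j] > 0:
                counts[key][0] += 1
            else:
                counts[key][1] += 1
    rows = [
        {
            "network_a": a,
            "network_b": b,
            "n_patient_gt_control": pos,
            "n_patient_lt_control": neg,
        }
        for (a, b), (pos, neg) in sorted(counts.items())
    ]
    return pd.DataFrame(rows)
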