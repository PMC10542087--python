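"""End-to-end orchestration: simulate -> preprocess -> window -> cluster ->
temporal -> nbs -> graph -> clinical -> report.

A `RunConfig` (built from YAML/JSON via `validate_config`) pins every
parameter and a mandatory master seed.  Per-stage seeds are derived from
the master seed by hashing the stage name, so adding or re-running a stage
never perturbs the randomness of earlier ones.  Every output table carries
the master seed and package version in a comment header, and the run report
records enough provenance to re-run the identical analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import correlate_clinical, describe_cohort
from .graphmetrics import (
    SparsityLadder,
    compare_variance,
    metric_variance,
    variance_table,
    window_metrics_auc,
)
from .io import default_network_map, preprocess
from .nbs import edgewise_glm, nbs, summarize_by_network
from .simulate import CohortConfig, generate_cohort, write_cohort
from .states import (
    compare_temporal,
    fit_states,
    select_k,
    state_mean_fc_cohort,
    temporal_metrics,
)
from .windows import WindowSpec, windowed_fc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "validate_config", "load_config", "run_pipeline",
           "STAGES"]

STAGES = (
    "simulate", "preprocess", "window", "cluster",
    "temporal", "nbs", "graph", "clinical", "report",
)

_VALID_KEYS = {
    "": {"seed", "outdir", "stages", "cohort", "window", "preprocess",
         "cluster", "nbs", "graph", "clinical"},
    "cohort": {f.name for f in dataclasses.fields(CohortConfig)} - {"seed"},
    "window": {"window_len", "step"},
    "preprocess": {"detrend", "band_low", "band_high"},
    "cluster": {"k", "k_range", "criterion", "n_restarts"},
    "nbs": {"edge_threshold_p", "component_p", "n_permutations", "covariates"},
    "graph": {"s_min", "s_max", "s_step", "rank", "max_windows"},
    "clinical": {"covariates"},
}


@dataclasses.dataclass
class RunConfig:
    """Validated, fully-defaulted configuration for one pipeline run."""

    seed: int
    outdir: str
    stages: tuple = STAGES
    cohort: dict = dataclasses.field(default_factory=dict)
    window: dict = dataclasses.field(default_factory=dict)
    preprocess: dict = dataclasses.field(default_factory=dict)
    cluster: dict = dataclasses.field(default_factory=dict)
    nbs: dict = dataclasses.field(default_factory=dict)
    graph: dict = dataclasses.field(default_factory=dict)
    clinical: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RunReport:
    """Per-stage provenance and headline numbers of a run."""

    config: dict
    version: str
    stages: dict

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "version": self.version, "stages": self.stages},
            indent=2, default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed: hash of 'master:stage', below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _check_keys(section: str, raw: Mapping) -> None:
    valid = _VALID_KEYS[section]
    unknown = set(raw) - valid
    if unknown:
        where = f"section '{section}'" if section else "top level"
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} at {where}; "
            f"valid keys: {sorted(valid)}"
        )


def validate_config(raw: Mapping) -> RunConfig:
    """Check keys and invariants, fill defaults, return a normalised RunConfig."""
    raw = dict(raw)
    _check_keys("", raw)
    if "seed" not in raw:
        raise ValueError("config must set 'seed' (seeds are mandatory)")
    seed = int(raw["seed"])
    outdir = str(raw.get("outdir", "dfcstates_run"))
    stages = tuple(raw.get("stages", STAGES))
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage '{st}'; valid stages: {list(STAGES)}")

    sections = {}
    for name in ("cohort", "window", "preprocess", "cluster", "nbs", "graph", "clinical"):
        sec = dict(raw.get(name, {}))
        _check_keys(name, sec)
        sections[name] = sec

    # defaults + invariant checks (constructors validate the rest)
    win = {"window_len": 30, "step": 3, **sections["window"]}
    WindowSpec(**win)
    pre = {"detrend": True, "band_low": 0.01, "band_high": 0.08, **sections["preprocess"]}
    clu = {"k": "auto", "k_range": [2, 8], "criterion": "elbow", "n_restarts": 50,
           **sections["cluster"]}
    if clu["k"] != "auto" and int(clu["k"]) < 2:
        raise ValueError("cluster.k must be 'auto' or an integer >= 2")
    nbs_sec = {"edge_threshold_p": 0.001, "component_p": 0.05, "n_permutations": 1000,
               "covariates": ["age", "sex", "education_years"], **sections["nbs"]}
    gr = {"s_min": 0.10, "s_max": 0.40, "s_step": 0.01, "rank": "abs",
          "max_windows": None, **sections["graph"]}
    SparsityLadder(gr["s_min"], gr["s_max"], gr["s_step"])  # raises on s_min >= s_max
    cli_sec = {"covariates": ["age", "sex", "education_years"], **sections["clinical"]}

    cohort = dict(sections["cohort"])
    CohortConfig(seed=0, **cohort).validate()

    return RunConfig(
        seed=seed, outdir=outdir, stages=stages, cohort=cohort,
        window=win, preprocess=pre, cluster=clu, nbs=nbs_sec, graph=gr,
        clinical=cli_sec,
    )


def load_config(path) -> RunConfig:
    """Parse a YAML or JSON config file and validate it."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return validate_config(raw)


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path: Path, seed: int, sep: str = ",") -> None:
    header = f"# dfcstates {__version__} seed={seed}\n"
    path.write_text(header + df.to_csv(index=False, sep=sep, float_format="%.10g"))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in canonical order.

    Any stage failure aborts with the stage name attached to the exception.
    Returns the run report (also written to ``<outdir>/run_report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    ctx: dict = {}
    report: dict = {}
    requested = [s for s in STAGES if s in config.stages]
    for stage in requested:
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[stage](config, ctx, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        info = info or {}
        info["seed"] = stage_seed(config.seed, stage)
        info["wall_seconds"] = round(time.perf_counter() - t0, 3)
        report[stage] = info
        logger.info("stage %s done in %.1fs", stage, info["wall_seconds"])

    run_report = RunReport(config=config.to_dict(), version=__version__, stages=report)
    (outdir / "run_report.json").write_text(run_report.to_json())
    return run_report


def _stage_simulate(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    cc = CohortConfig(seed=stage_seed(config.seed, "simulate"), **config.cohort)
    series, meta, truth = generate_cohort(cc)
    cohort_dir = outdir / "cohort"
    write_cohort(cohort_dir, series, meta, truth)
    ctx.update(series=series, meta=meta, truth=truth, cohort_cfg=cc)
    return {"n_subjects": len(series), "n_regions": cc.n_regions,
            "n_volumes": cc.n_volumes, "outputs": str(cohort_dir)}


def _stage_preprocess(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    if "series" not in ctx:
        raise ValueError("preprocess needs the simulate stage (or loaded series)")
    cc = ctx["cohort_cfg"]
    pre = config.preprocess
    band = (pre["band_low"], pre["band_high"])
    ctx["preprocessed"] = [
        preprocess(ts, n_discard=cc.n_discard, detrend=pre["detrend"], band=band)
        for ts in ctx["series"]
    ]
    return {"n_discard": cc.n_discard, "detrend": pre["detrend"], "band": list(band)}


def _stage_window(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    if "preprocessed" not in ctx:
        raise ValueError("window needs the preprocess stage")
    spec = WindowSpec(**config.window)
    wfcs = [windowed_fc(ts, spec) for ts in ctx["preprocessed"]]
    ctx["wfcs"] = wfcs
    ctx["window_spec"] = spec
    summary = pd.DataFrame(
        {"subject_id": [w.subject_id for w in wfcs],
         "n_windows": [w.n_windows for w in wfcs]}
    )
    _write_table(summary, outdir / "windows_summary.csv", config.seed)
    total = int(summary["n_windows"].sum())
    return {"windows_per_subject": int(summary["n_windows"].iloc[0]),
            "total_windowed_networks": total}


def _stage_cluster(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    if "wfcs" not in ctx:
        raise ValueError("cluster needs the window stage")
    seed = stage_seed(config.seed, "cluster")
    clu = config.cluster
    info: dict = {}
    if clu["k"] == "auto":
        lo, hi = clu["k_range"]
        k, curve, flat = select_k(
            ctx["wfcs"], range(int(lo), int(hi) + 1),
            criterion=clu["criterion"], seed=seed,
        )
        info["validity_curve"] = {int(kk): float(v) for kk, v in curve.items()}
        info["flat_curve_warning"] = bool(flat)
        _write_table(
            pd.DataFrame({"k": list(curve), "criterion": list(curve.values())}),
            outdir / "k_selection.csv", config.seed,
        )
    else:
        k = int(clu["k"])
    model = fit_states(ctx["wfcs"], k, n_restarts=int(clu["n_restarts"]), seed=seed)
    ctx["state_model"] = model
    _write_table(
        pd.DataFrame(model.centroids), outdir / "state_centroids.tsv",
        config.seed, sep="\t",
    )
    labels_rows = [
        {"subject_id": sid, "window_index": i, "state": int(s)}
        for sid, seq in model.labels.items() for i, s in enumerate(seq)
    ]
    _write_table(pd.DataFrame(labels_rows), outdir / "state_labels.csv", config.seed)
    info.update(k=int(k), inertia=float(model.inertia))
    return info


def _stage_temporal(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    if "state_model" not in ctx:
        raise ValueError("temporal needs the cluster stage")
    model = ctx["state_model"]
    metrics = temporal_metrics(model.labels, model.k)
    ctx["temporal_metrics"] = metrics
    _write_table(metrics, outdir / "temporal_metrics.csv", config.seed)
    contrasts = compare_temporal(
        metrics, ctx["meta"], covariates=tuple(config.clinical["covariates"])
    )
    ctx["temporal_contrasts"] = contrasts
    _write_table(contrasts, outdir / "temporal_contrasts.csv", config.seed)
    sig = contrasts[contrasts["p"] < 0.05]["metric"].tolist()
    return {"significant_metrics": sig}


def _stage_nbs(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    if "state_model" not in ctx:
        raise ValueError("nbs needs the cluster stage")
    model = ctx["state_model"]
    seed = stage_seed(config.seed, "nbs")
    cfg = config.nbs
    labels = list(ctx["wfcs"][0].region_labels)
    netmap = default_network_map(labels)
    info: dict = {}
    for state in range(1, model.k + 1):
        mats = state_mean_fc_cohort(ctx["wfcs"], model, state)
        try:
            result = nbs(
                mats, ctx["meta"], covariates=tuple(cfg["covariates"]),
                edge_threshold_p=cfg["edge_threshold_p"],
                n_permutations=int(cfg["n_permutations"]),
                seed=seed + state, state=state,
            )
            stats = edgewise_glm(
                mats, ctx["meta"], covariates=tuple(cfg["covariates"]), state=state
            )
        except ValueError as exc:
            info[f"state_{state}"] = {"skipped": str(exc)}
            continue
        payload = {
            "state": state,
            "edge_threshold_p": cfg["edge_threshold_p"],
            "n_permutations": int(cfg["n_permutations"]),
            "components": [
                {
                    "edges": [[labels[i], labels[j]] for i, j in c["edges"]],
                    "size": c["size"],
                    "fwe_p": c["fwe_p"],
                }
                for c in result.components
            ],
        }
        (outdir / f"nbs_state{state}.json").write_text(json.dumps(payload, indent=2))
        sig = [c for c in result.components if c["fwe_p"] < cfg["component_p"]]
        if sig:
            summary = summarize_by_network(sig, stats.t_values, labels, netmap)
            _write_table(summary, outdir / f"nbs_state{state}_networks.tsv",
                         config.seed, sep="\t")
        info[f"state_{state}"] = {
            "n_components": len(result.components),
            "n_significant": len(sig),
            "n_per_group": stats.n_per_group,
        }
    return info


def _stage_graph(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    if "wfcs" not in ctx:
        raise ValueError("graph needs the window stage")
    gr = config.graph
    ladder = SparsityLadder(gr["s_min"], gr["s_max"], gr["s_step"])
    max_windows = gr["max_windows"]
    variances = {}
    for w in ctx["wfcs"]:
        z = w.z if max_windows is None else w.z[: int(max_windows)]
        auc = window_metrics_auc(z, ladder, rank=gr["rank"])
        variances[w.subject_id] = metric_variance(auc)
    labels = list(ctx["wfcs"][0].region_labels)
    table = variance_table(variances, labels)
    _write_table(table, outdir / "metric_variance.csv", config.seed)
    contrasts = compare_variance(
        table, ctx["meta"], covariates=tuple(config.clinical["covariates"])
    )
    ctx["variance_contrasts"] = contrasts
    _write_table(contrasts, outdir / "variance_contrasts.csv", config.seed)
    n_disc = int(contrasts["significant"].sum())
    return {"ladder_rungs": int(ladder.values().size),
            "windows_used": "all" if max_windows is None else int(max_windows),
            "n_discoveries": n_disc}


def _stage_clinical(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    meta = ctx.get("meta")
    if meta is None:
        raise ValueError("clinical needs cohort metadata")
    summary = describe_cohort(meta)
    _write_table(summary, outdir / "cohort_summary.csv", config.seed)
    info: dict = {"n_correlation_tests": 0}
    if "temporal_metrics" in ctx:
        metrics = ctx["temporal_metrics"]
        pat = meta[meta["group"] == "patient"]
        merged = metrics.merge(pat, on="subject_id")
        rows = []
        metric_cols = [c for c in metrics.columns if c.startswith(("mdt_", "frac_"))]
        metric_cols += ["n_transitions"]
        for score in ("joa", "ndi"):
            if score not in merged.columns:
                continue
            for col in metric_cols:
                try:
                    cc = correlate_clinical(
                        merged[col], merged[score], metric_name=col, score_name=score
                    )
                except ValueError:
                    continue
                rows.append(dataclasses.asdict(cc))
        if rows:
            corr = pd.DataFrame(rows)
            _write_table(corr, outdir / "clinical_correlations.csv", config.seed)
            info["n_correlation_tests"] = len(rows)
            info["n_significant_correlations"] = int((corr["p"] < 0.05).sum())
    return info


def _stage_report(config: RunConfig, ctx: dict, outdir: Path) -> dict:
    files = sorted(p.name for p in outdir.iterdir() if p.is_file())
    return {"outputs": files}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "window": _stage_window,
    "cluster": _stage_cluster,
    "temporal": _stage_temporal,
    "nbs": _stage_nbs,
    "graph": _stage_graph,
    "clinical": _stage_clinical,
    "report": _stage_report,
}
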