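"""Synthetic two-group cohort with planted connectivity states.

Generative model
----------------
Real resting-state cohorts for dynamic-connectivity studies have no public
ground truth, so every downstream stage here is validated against a cohort
with *planted* structure.  The model is the minimal one that makes windowed
correlation states, dwell times and a group dwell-time asymmetry all
well-defined:

* a hidden Markov chain over K connectivity states whose ticks advance every
  ``state_switch_step`` volumes (default 3, matching the sliding-window step,
  so latent dwell times are commensurate with window-level state labels);
* within a dwell segment, the N-region signal is drawn i.i.d. from a
  zero-mean multivariate normal with that state's covariance;
* an AR(1)-smoothed observation noise of stationary standard deviation
  ``noise_sd`` is added on top.

State covariances are correlation matrices with elevated within-module
blocks; each state splits the modules into two anticorrelated
super-communities by a distinct Hadamard-style sign pattern (the first
state is the globally integrated, all-positive pattern), so the K states
differ by which networks are coupled — a cartoon of the large-scale
integration/segregation re-configuration seen across empirical
connectivity states.

The planted group difference is confined to the self-transition probability
of one state ("state 2", index 1): patients (group A) dwell longer there
than controls, mirroring the kind of single-state mean-dwell-time asymmetry
reported in clinical dynamic-connectivity studies.  The asymmetry is
realised by *lowering* the controls' self-transition in that state below
the shared baseline (rather than raising the patients'), which keeps
patient dwell segments short relative to the scan so their dwell times are
not truncated by the acquisition window.  Everything else is matched
between groups.

Defaults emulate a cohort of 88 patients and 77 controls, 90 regions,
240 volumes at TR = 2 s with the first 10 volumes discarded downstream.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    RoiTimeSeries,
    default_region_labels,
    write_timeseries,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_state_sequence",
    "default_module_labels",
    "default_block_covariances",
    "default_transition_matrix",
    "generate_cohort",
    "write_cohort",
    "load_ground_truth",
]

# Cohort-level demographic moments used as generator defaults
# (two-group means/SDs for age, education, symptom duration, clinical scores).
_PATIENT_AGE = (49.22, 7.91)
_CONTROL_AGE = (45.13, 8.76)
_PATIENT_EDU = (12.91, 1.21)
_CONTROL_EDU = (12.64, 1.20)
_PATIENT_MALE_FRAC = 45 / 88
_CONTROL_MALE_FRAC = 39 / 77
_DURATION = (10.24, 6.10)
_JOA = (11.10, 1.78)
_NDI = (0.32, 0.09)


@dataclasses.dataclass
class CohortConfig:
    """Study-condition parameters for the synthetic cohort.

    Attributes
    ----------
    n_group_a, n_group_b : int
        Group sizes; group A plays the patient role, group B the controls.
    n_regions, n_volumes, n_discard : int
        Parcellation size, acquired volumes, and volumes discarded downstream.
    tr_seconds : float
        Repetition time in seconds.
    n_states : int
        Number of latent connectivity states (>= 1; 1 is the degenerate
        single-state case).
    state_covariances : list of ndarray, optional
        One N x N PSD covariance per state; defaults to
        `default_block_covariances` over 8 contiguous modules.
    transition_matrix_a, transition_matrix_b : ndarray, optional
        K x K row-stochastic matrices per group; defaults plant a higher
        self-transition for group A in state 2 only.
    state_switch_step : int
        Volumes per latent dwell tick.
    noise_sd : float
        Stationary SD of the AR(1) observation noise.
    noise_ar : float
        AR(1) coefficient of the observation noise.
    seed : int
        Mandatory RNG seed; the whole cohort is a pure function of it.
    """

    seed: int
    n_group_a: int = 88
    n_group_b: int = 77
    n_regions: int = 90
    n_volumes: int = 240
    n_discard: int = 10
    tr_seconds: float = 2.0
    n_states: int = 4
    state_covariances: list | None = None
    transition_matrix_a: np.ndarray | None = None
    transition_matrix_b: np.ndarray | None = None
    state_switch_step: int = 3
    noise_sd: float = 0.5
    noise_ar: float = 0.3
    within_r: float = 0.5
    between_r: float = 0.35
    planted_state: int = 2          # 1-based; the state with the dwell asymmetry
    p_self: float = 0.96            # baseline self-transition per tick
    p_self_planted_a: float = 0.96  # group A (patient) self-transition in the planted state
    p_self_planted_b: float = 0.90  # group B (control) self-transition in the planted state

    def validate(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed n_discard")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.state_switch_step < 1:
            raise ValueError("state_switch_step must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.noise_ar < 1:
            raise ValueError("noise_ar must be in [0, 1)")
        if self.n_states >= 2 and not 1 <= self.planted_state <= self.n_states:
            raise ValueError("planted_state out of range")
        for mat in (self.transition_matrix_a, self.transition_matrix_b):
            if mat is not None:
                _check_stochastic(np.asarray(mat), self.n_states)
        if self.state_covariances is not None:
            if len(self.state_covariances) != self.n_states:
                raise ValueError("need one covariance per state")
            for cov in self.state_covariances:
                _check_psd(np.asarray(cov), self.n_regions)


@dataclasses.dataclass
class GroundTruth:
    """Truth channel for tests: what the generator actually planted.

    ``latent`` holds, per subject, the 1-based latent state of every
    *retained* volume (the first ``n_discard`` volumes are trimmed so the
    sequence aligns with preprocessed series).
    """

    latent: dict
    transition_matrix_a: np.ndarray
    transition_matrix_b: np.ndarray
    module_labels: np.ndarray
    planted_state: int
    state_covariances: list

    def to_json(self) -> str:
        payload = {
            "latent": {k: np.asarray(v).tolist() for k, v in self.latent.items()},
            "transition_matrix_a": np.asarray(self.transition_matrix_a).tolist(),
            "transition_matrix_b": np.asarray(self.transition_matrix_b).tolist(),
            "module_labels": np.asarray(self.module_labels).tolist(),
            "planted_state": int(self.planted_state),
        }
        return json.dumps(payload)


def _check_stochastic(mat: np.ndarray, k: int) -> None:
    if mat.shape != (k, k):
        raise ValueError(f"transition matrix must be {k}x{k}, got {mat.shape}")
    if (mat < 0).any():
        raise ValueError("transition probabilities must be non-negative")
    rows = mat.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise ValueError(f"transition matrix rows must sum to 1, got {rows}")


def _check_psd(cov: np.ndarray, n: int) -> None:
    if cov.shape != (n, n):
        raise ValueError(f"covariance must be {n}x{n}, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10:
        raise ValueError(f"covariance not PSD (min eigenvalue {w.min():.3g})")


# ---------------------------------------------------------------------------
# Latent chain
# ---------------------------------------------------------------------------

def generate_state_sequence(
    transition_matrix: np.ndarray,
    n_ticks: int,
    initial_distribution: np.ndarray | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a 1-based latent state sequence from a Markov chain.

    Parameters
    ----------
    transition_matrix : ndarray, shape (K, K)
        Row-stochastic; K >= 2.
    n_ticks : int
        Sequence length (>= 1).
    initial_distribution : ndarray, optional
        Distribution of the first state; uniform by default.
    seed, rng
        Either an integer seed or an existing Generator (rng wins).
    """
    mat = np.asarray(transition_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("transition matrix must be square")
    k = mat.shape[0]
    if k < 2:
        raise ValueError("Markov chain needs K >= 2 states")
    _check_stochastic(mat, k)
    if n_ticks < 1:
        raise ValueError("n_ticks must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if initial_distribution is None:
        initial_distribution = np.full(k, 1.0 / k)
    init = np.asarray(initial_distribution, dtype=float)
    if init.shape != (k,) or not np.isclose(init.sum(), 1.0, atol=1e-9):
        raise ValueError("initial_distribution must be a length-K probability vector")

    cum = np.cumsum(mat, axis=1)
    u = rng.random(n_ticks)
    seq = np.empty(n_ticks, dtype=np.int64)
    state = int(np.searchsorted(np.cumsum(init), u[0], side="right"))
    state = min(state, k - 1)
    seq[0] = state
    for t in range(1, n_ticks):
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, k - 1)
        seq[t] = state
    return seq + 1


def default_transition_matrix(
    n_states: int, p_self: float = 0.9, p_self_overrides: dict | None = None
) -> np.ndarray:
    """Uniform-off-diagonal chain with per-state self-transition probability.

    ``p_self_overrides`` maps 1-based state -> self-transition probability.
    """
    if n_states == 1:
        return np.array([[1.0]])
    mat = np.empty((n_states, n_states))
    for i in range(n_states):
        ps = p_self
        if p_self_overrides and (i + 1) in p_self_overrides:
            ps = p_self_overrides[i + 1]
        mat[i] = (1 - ps) / (n_states - 1)
        mat[i, i] = ps
    return mat


# ---------------------------------------------------------------------------
# State covariances
# ---------------------------------------------------------------------------

def default_module_labels(n_regions: int, n_modules: int = 8) -> np.ndarray:
    """Contiguous near-equal module assignment, 0-based module ids."""
    bounds = np.linspace(0, n_regions, n_modules + 1).round().astype(int)
    labels = np.empty(n_regions, dtype=np.int64)
    for j in range(n_modules):
        labels[bounds[j]:bounds[j + 1]] = j
    return labels


# state-dependent within-module contrast: strongly-knit modules sit at
# within_r * _HUB_HI, weakly-knit at within_r * _HUB_LO.  The weak level must
# stay above |between_r| or the matrix leaves the PSD cone and shrinkage
# washes out the planted structure (0.8 * 0.5 = 0.40 > 0.35 at defaults).
_HUB_HI = 1.3
_HUB_LO = 0.8


def _sign_vector(n_modules: int, row: int) -> np.ndarray:
    """Hadamard-style +/-1 pattern over modules; row 0 is all +1."""
    row = row % n_modules
    if row == 0:
        return np.ones(n_modules)
    return np.array(
        [1.0 if ((m >> (row - 1)) & 1) == 0 else -1.0 for m in range(n_modules)]
    )


def default_block_covariances(
    n_regions: int,
    module_labels: Sequence[int] | None = None,
    within_r: float = 0.5,
    between_r: float = 0.35,
    n_states: int = 4,
) -> list:
    """Build one correlation matrix per state from a module structure.

    Two features distinguish the states:

    * **Between-module sign pattern** — state ``s`` splits the M modules
      into two super-communities by a Hadamard-style sign vector (state 1
      is the globally integrated pattern where all modules couple
      positively), with coupling ``+between_r`` inside a super-community
      and ``-between_r`` across.  Any two states then differ over roughly
      half of all between-module edges, which makes the planted partition
      recoverable by clustering.
    * **Within-module strong/weak contrast** — each state also designates
      half the modules as strongly knit (``within_r * 1.3``) and half as
      weakly knit (``within_r * 0.8``) by a second, state-shifted sign
      vector.  Because within-module edges top the |Z| ranking, the
      binarised graph topology genuinely re-wires when the state switches.

    Together these mirror how empirical connectivity states differ:
    large-scale integration/segregation re-arrangements spanning many
    networks, including anticorrelated blocks.  Matrices are symmetric
    with unit diagonal and are shrunk toward the identity until positive
    semidefinite (error if 200 shrinkage steps do not suffice); the
    defaults need no shrinkage.
    """
    if not (abs(within_r) < 1 and abs(between_r) < 1):
        raise ValueError("|within_r| and |between_r| must be < 1")
    if module_labels is None:
        module_labels = default_module_labels(n_regions)
    labels = np.asarray(module_labels)
    if labels.shape != (n_regions,):
        raise ValueError("module_labels must have one entry per region")
    modules = np.unique(labels)
    n_modules = len(modules)

    covs = []
    for s in range(n_states):
        cov = np.eye(n_regions)
        hub = _sign_vector(n_modules, s + 1)  # which modules are strongly knit
        for mi, m in enumerate(modules):
            idx = np.flatnonzero(labels == m)
            block = np.ix_(idx, idx)
            # within-module coupling alternates strong/weak per state, so the
            # top-ranked (within-module) edges re-wire when the state
            # switches and binarised topology genuinely varies with state
            if n_modules >= 2:
                w = within_r * (_HUB_HI if hub[mi] > 0 else _HUB_LO)
            else:
                w = within_r
            cov[block] = np.clip(w, -0.99, 0.99)
            cov[idx, idx] = 1.0
        if n_modules >= 2 and between_r != 0:
            row = s % n_modules
            flip = -1.0 if (s // n_modules) % 2 else 1.0
            u = _sign_vector(n_modules, row)
            for a in range(n_modules):
                for b in range(a + 1, n_modules):
                    ia = np.flatnonzero(labels == modules[a])
                    ib = np.flatnonzero(labels == modules[b])
                    v = flip * u[a] * u[b] * between_r
                    cov[np.ix_(ia, ib)] = v
                    cov[np.ix_(ib, ia)] = v
        covs.append(_shrink_to_psd(cov))
    return covs


def _shrink_to_psd(cov: np.ndarray, max_steps: int = 200) -> np.ndarray:
    """Shrink toward the identity until the minimum eigenvalue is >= -1e-12."""
    out = cov.copy()
    eye = np.eye(cov.shape[0])
    for _ in range(max_steps):
        if np.linalg.eigvalsh(out).min() >= -1e-12:
            return out
        out = 0.95 * out + 0.05 * eye
    raise ValueError("could not reach a PSD matrix by shrinkage")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _resolve(config: CohortConfig):
    """Fill in default covariances and transition matrices."""
    covs = config.state_covariances
    if covs is None:
        covs = default_block_covariances(
            config.n_regions,
            within_r=config.within_r,
            between_r=config.between_r,
            n_states=config.n_states,
        )
        modules = default_module_labels(config.n_regions)
    else:
        covs = [np.asarray(c, dtype=float) for c in covs]
        modules = default_module_labels(config.n_regions)
    mat_a = config.transition_matrix_a
    if mat_a is None:
        mat_a = default_transition_matrix(
            config.n_states,
            config.p_self,
            {config.planted_state: config.p_self_planted_a},
        )
    mat_b = config.transition_matrix_b
    if mat_b is None:
        mat_b = default_transition_matrix(
            config.n_states,
            config.p_self,
            {config.planted_state: config.p_self_planted_b},
        )
    return covs, np.asarray(mat_a, float), np.asarray(mat_b, float)


def _ar1_noise(rng: np.random.Generator, t: int, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros((t, n))
    innov_sd = sd * np.sqrt(1 - phi**2)
    e = np.empty((t, n))
    e[0] = sd * rng.standard_normal(n)
    z = innov_sd * rng.standard_normal((t - 1, n))
    for i in range(1, t):
        e[i] = phi * e[i - 1] + z[i - 1]
    return e


def _subject_series(
    rng: np.random.Generator,
    latent_volumes: np.ndarray,
    chols: list,
    noise_sd: float,
    noise_ar: float,
) -> np.ndarray:
    t = latent_volumes.size
    n = chols[0].shape[0]
    out = np.empty((t, n))
    # draw each maximal dwell segment from that state's covariance
    change = np.flatnonzero(np.diff(latent_volumes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [t]))
    for s, e in zip(starts, ends):
        state = latent_volumes[s] - 1
        z = rng.standard_normal((e - s, n))
        out[s:e] = z @ chols[state].T
    out += _ar1_noise(rng, t, n, noise_sd, noise_ar)
    return out


def generate_cohort(config: CohortConfig):
    """Generate the cohort: (list of RoiTimeSeries, metadata DataFrame, GroundTruth).

    Deterministic for a fixed seed: each subject draws from an independent
    stream spawned from the master seed, so the cohort is reproducible and
    subjects are statistically independent.
    """
    config.validate()
    covs, mat_a, mat_b = _resolve(config)
    for cov in covs:
        _check_psd(cov, config.n_regions)
    chols = []
    for cov in covs:
        # tiny jitter keeps Cholesky defined for exactly-singular PSD inputs
        w = np.linalg.eigvalsh(cov).min()
        jitter = max(0.0, 1e-10 - w)
        chols.append(np.linalg.cholesky(cov + (jitter + 1e-12) * np.eye(len(cov))))

    labels = default_region_labels(config.n_regions)
    n_total = config.n_group_a + config.n_group_b
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_total + 1)
    meta_rng = np.random.default_rng(children[-1])

    n_ticks = -(-config.n_volumes // config.state_switch_step)  # ceil division
    series: list[RoiTimeSeries] = []
    latent_truth: dict[str, np.ndarray] = {}
    rows = []
    for idx in range(n_total):
        is_patient = idx < config.n_group_a
        sid = f"sub-{'A' if is_patient else 'B'}{(idx if is_patient else idx - config.n_group_a) + 1:03d}"
        rng = np.random.default_rng(children[idx])
        if config.n_states == 1:
            ticks = np.ones(n_ticks, dtype=np.int64)
        else:
            ticks = generate_state_sequence(
                mat_a if is_patient else mat_b, n_ticks, rng=rng
            )
        latent_volumes = np.repeat(ticks, config.state_switch_step)[: config.n_volumes]
        data = _subject_series(rng, latent_volumes, chols, config.noise_sd, config.noise_ar)
        series.append(RoiTimeSeries(sid, data, labels, config.tr_seconds))
        latent_truth[sid] = latent_volumes[config.n_discard:]
        rows.append(_subject_meta(meta_rng, sid, is_patient))

    meta = pd.DataFrame(rows)
    truth = GroundTruth(
        latent=latent_truth,
        transition_matrix_a=mat_a,
        transition_matrix_b=mat_b,
        module_labels=default_module_labels(config.n_regions),
        planted_state=config.planted_state,
        state_covariances=covs,
    )
    return series, meta, truth


def _subject_meta(rng: np.random.Generator, sid: str, is_patient: bool) -> dict:
    age_m, age_s = _PATIENT_AGE if is_patient else _CONTROL_AGE
    edu_m, edu_s = _PATIENT_EDU if is_patient else _CONTROL_EDU
    male_frac = _PATIENT_MALE_FRAC if is_patient else _CONTROL_MALE_FRAC
    row = {
        "subject_id": sid,
        "group": "patient" if is_patient else "control",
        "age": float(np.clip(rng.normal(age_m, age_s), 18, 80)),
        "sex": "M" if rng.random() < male_frac else "F",
        "education_years": float(np.clip(rng.normal(edu_m, edu_s), 6, 20)),
    }
    if is_patient:
        row["duration_months"] = float(np.clip(rng.normal(*_DURATION), 0.5, None))
        row["joa"] = float(np.clip(rng.normal(*_JOA), 0, 17))
        row["ndi"] = float(np.clip(rng.normal(*_NDI), 0, 1))
    else:
        # clinical scales are administered to patients only
        row["duration_months"] = np.nan
        row["joa"] = np.nan
        row["ndi"] = np.nan
    return row


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_cohort(outdir, series, meta: pd.DataFrame, truth: GroundTruth) -> None:
    """Write one TSV per subject, participants.csv, and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ts in series:
        write_timeseries(ts, outdir / f"{ts.subject_id}.tsv")
    meta.to_csv(outdir / "participants.csv", index=False)
    (outdir / "ground_truth.json").write_text(truth.to_json())


def load_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
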