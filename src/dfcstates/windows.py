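"""Sliding-window functional connectivity and its across-window variability.

One connectivity matrix per window: Pearson correlation between all region
pairs over the window's volumes, Fisher-Z transformed (arctanh) off the
diagonal.  With the conventional 30-volume window advanced by 3 volumes over
230 retained volumes this yields 67 windows per subject.  Windows are
rectangular (untapered) and indexed 0-based with half-open intervals.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .io import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "WindowedFC",
    "VariabilityMap",
    "enumerate_windows",
    "fisher_z",
    "windowed_fc",
    "variability_map",
    "upper_vec",
    "vec_to_matrix",
]

_CLAMP = 1.0 - 1e-7  # keeps arctanh finite for duplicate columns


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in volumes (defaults: 30-volume window, step 3)."""

    window_len: int = 30
    step: int = 3

    def __post_init__(self):
        if self.window_len < 3:
            raise ValueError("window_len must be >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def n_windows(self, t: int) -> int:
        if self.window_len > t:
            raise ValueError(f"window_len {self.window_len} exceeds T={t}")
        return (t - self.window_len) // self.step + 1


@dataclasses.dataclass(frozen=True)
class WindowedFC:
    """Stack of per-window Fisher-Z connectivity matrices for one subject.

    ``z`` has shape (W, N, N): symmetric, zero diagonal, Fisher-Z units.
    ``windows`` holds the half-open (start, end) volume intervals.
    """

    subject_id: str
    windows: tuple
    z: np.ndarray
    region_labels: tuple

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def n_regions(self) -> int:
        return self.z.shape[1]


@dataclasses.dataclass(frozen=True)
class VariabilityMap:
    """Across-window standard deviation of the Fisher-Z value per edge."""

    subject_id: str
    sd_z: np.ndarray
    region_labels: tuple


def enumerate_windows(t: int, spec: WindowSpec) -> tuple:
    """Half-open volume intervals [k*step, k*step + window_len), k = 0..W-1.

    W = floor((T - window_len) / step) + 1, so the last window always fits.
    """
    w = spec.n_windows(t)
    return tuple(
        (k * spec.step, k * spec.step + spec.window_len) for k in range(w)
    )


def fisher_z(r):
    """Variance-stabilising arctanh transform of a Pearson correlation.

    Values with |r| >= 1 - 1e-7 are clamped before the transform so the
    result stays finite (duplicate regions must not poison clustering).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    return np.arctanh(np.clip(r, -_CLAMP, _CLAMP))


def windowed_fc(ts: RoiTimeSeries, spec: WindowSpec = WindowSpec()) -> WindowedFC:
    """Per-window Pearson correlation -> Fisher-Z, diagonal set to 0.

    A region with zero variance inside a window gets correlation 0 with
    everything in that window (logged as a warning) rather than NaN.
    """
    intervals = enumerate_windows(ts.n_volumes, spec)
    n = ts.n_regions
    z = np.empty((len(intervals), n, n))
    for w, (a, b) in enumerate(intervals):
        seg = ts.data[a:b]
        sd = seg.std(axis=0)
        # relative tolerance: a numerically-constant region has sd at rounding level
        degenerate = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(seg).max(axis=0)))
        if degenerate.size:
            logger.warning(
                "subject %s window [%d,%d): zero-variance regions %s; "
                "their correlations set to 0",
                ts.subject_id, a, b,
                [ts.region_labels[i] for i in degenerate],
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg, rowvar=False)
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
        np.clip(r, -1.0, 1.0, out=r)
        zw = fisher_z(r)
        np.fill_diagonal(zw, 0.0)
        z[w] = 0.5 * (zw + zw.T)  # enforce exact symmetry
    return WindowedFC(ts.subject_id, intervals, z, ts.region_labels)


def variability_map(wfc: WindowedFC) -> VariabilityMap:
    """Entrywise sample SD (ddof=1) of Z across windows — the dFC variability map."""
    if wfc.n_windows < 2:
        raise ValueError("variability needs at least 2 windows")
    sd = wfc.z.std(axis=0, ddof=1)
    np.fill_diagonal(sd, 0.0)
    return VariabilityMap(wfc.subject_id, sd, wfc.region_labels)


# ---------------------------------------------------------------------------
# Vectorisation helpers: strictly off-diagonal upper triangle, row-major order
# ---------------------------------------------------------------------------

def upper_vec(matrices: np.ndarray) -> np.ndarray:
    """Extract upper-triangle (k=1) vectors from (..., N, N) matrices."""
    matrices = np.asarray(matrices)
    n = matrices.shape[-1]
    iu = np.triu_indices(n, k=1)
    return matrices[..., iu[0], iu[1]]


def vec_to_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    """Rebuild a symmetric zero-diagonal N x N matrix from an upper-triangle vector."""
    out = np.zeros(vec.shape[:-1] + (n, n))
    iu = np.triu_indices(n, k=1)
    out[..., iu[0], iu[1]] = vec
    out[..., iu[1], iu[0]] = vec
    return out
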