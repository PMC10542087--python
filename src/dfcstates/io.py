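"""Reading, writing and temporal preprocessing of parcellated ROI time series.

The package's contract begins at the parcellated signal: a T x N matrix of
one column per brain region (e.g. the 90 regions of an AAL-style atlas),
already extracted from images upstream.  The in-scope temporal steps are the
ones that act on such a matrix directly: discarding initial volumes acquired
before signal equilibrium, removing per-region linear trends, and band-pass
filtering to the low-frequency band where resting-state fluctuations live
(conventionally 0.01-0.08 Hz).  Voxel-level operations (realignment, spatial
normalisation, smoothing, nuisance-image regression) are out of scope.

The fixed preprocessing order is discard -> detrend -> band-pass; each step
can be switched off but the order is not configurable, because detrending
before filtering avoids edge transients from large slow drifts.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RoiTimeSeries",
    "NetworkMap",
    "load_timeseries",
    "write_timeseries",
    "discard_initial",
    "detrend_linear",
    "bandpass",
    "preprocess",
    "default_region_labels",
    "default_network_map",
    "load_network_map",
    "write_network_map",
]

DEFAULT_NETWORKS = ("SMN", "DMN", "ECN", "SN", "VN", "AN", "LN", "PN")


@dataclasses.dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's parcellated signal: T timepoints by N regions.

    Parameters
    ----------
    subject_id : str
        Stable identifier used to align with metadata tables.
    data : ndarray, shape (T, N)
        Signal in arbitrary units; no missing values allowed.
    region_labels : tuple of str
        Unique region names, one per column, in column order.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    """

    subject_id: str
    data: np.ndarray
    region_labels: tuple
    tr_seconds: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {data.shape}")
        t, n = data.shape
        # T = 1 is permitted so that discarding down to a single retained
        # volume stays representable; analysis operations enforce their own
        # stronger minimums.
        if t < 1 or n < 2:
            raise ValueError(f"need T >= 1 and N >= 2, got T={t}, N={n}")
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n} columns"
            )
        if len(set(self.region_labels)) != n:
            raise ValueError("region labels must be unique")
        if not np.isfinite(data).all():
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        """Copy of this series with new data, same labels and TR."""
        return RoiTimeSeries(self.subject_id, data, self.region_labels, self.tr_seconds)


def default_region_labels(n_regions: int) -> tuple:
    return tuple(f"R{i + 1:03d}" for i in range(n_regions))


@dataclasses.dataclass(frozen=True)
class NetworkMap:
    """Mapping from region label to functional-network name.

    Unmapped regions are permitted; they are reported under ``"unmapped"``
    by summaries that group edges or nodes by network.
    """

    mapping: Mapping[str, str]

    def network_of(self, label: str) -> str | None:
        return self.mapping.get(label)

    def networks(self) -> tuple:
        seen: list[str] = []
        for name in self.mapping.values():
            if name not in seen:
                seen.append(name)
        return tuple(seen)

    def unmapped(self, labels: Sequence[str]) -> tuple:
        return tuple(lab for lab in labels if lab not in self.mapping)


def default_network_map(
    region_labels: Sequence[str], networks: Sequence[str] = DEFAULT_NETWORKS
) -> NetworkMap:
    """Assign regions to networks in contiguous, near-equal blocks.

    Stand-in for an atlas-specific lookup: real analyses should load the
    region->network table for their parcellation with `load_network_map`.
    """
    n = len(region_labels)
    m = len(networks)
    bounds = np.linspace(0, n, m + 1).round().astype(int)
    mapping: dict[str, str] = {}
    for j, name in enumerate(networks):
        for i in range(bounds[j], bounds[j + 1]):
            mapping[region_labels[i]] = name
    return NetworkMap(mapping)


def load_network_map(path) -> NetworkMap:
    df = pd.read_csv(path)
    if not {"region_label", "network"} <= set(df.columns):
        raise ValueError("network map CSV needs columns region_label, network")
    return NetworkMap(dict(zip(df["region_label"].astype(str), df["network"].astype(str))))


def write_network_map(nm: NetworkMap, path) -> None:
    pd.DataFrame(
        {"region_label": list(nm.mapping), "network": list(nm.mapping.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tabular I/O.  Dialect: tab-separated, header row of region labels, one row
# per volume.
# ---------------------------------------------------------------------------

def load_timeseries(path, expected_tr: float, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a T x N tab-separated time-series file with a header row.

    Raises a parse error naming the offending (row, column) for the first
    non-numeric cell, and a validation error for duplicate region labels.
    """
    path = Path(path)
    # read the header line directly: pandas silently mangles duplicate names
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise ValueError(f"duplicate region labels in {path.name}: {dupes}")
    df = pd.read_csv(path, sep="\t", header=0, names=labels)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell in {path.name} at data row {r}, column '{labels[c]}'"
        )
    if subject_id is None:
        subject_id = path.stem
    return RoiTimeSeries(subject_id, numeric.to_numpy(float), labels, expected_tr)


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    """Write the TSV dialect read by `load_timeseries` (lossless round-trip)."""
    df = pd.DataFrame(ts.data, columns=list(ts.region_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Temporal preprocessing
# ---------------------------------------------------------------------------

def discard_initial(ts: RoiTimeSeries, n_discard: int) -> RoiTimeSeries:
    """Drop the first `n_discard` volumes (scanner equilibration period)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_volumes} volumes"
        )
    if n_discard == 0:
        return ts
    return ts.with_data(ts.data[n_discard:])


def detrend_linear(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Subtract each region's least-squares line over the volume index.

    Idempotent; residuals have zero mean per region. The regressor is the
    0-based volume index (physical time is not needed for a line fit).
    """
    if ts.n_volumes < 3:
        raise ValueError("detrending needs at least 3 volumes")
    return ts.with_data(sps.detrend(ts.data, axis=0, type="linear"))


def bandpass(ts: RoiTimeSeries, low_hz: float, high_hz: float) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass, identical filter per region.

    Order-2 Butterworth applied forward and backward (`sosfiltfilt`), so
    there is no phase shift that could displace state-transition timing.
    With ``low_hz == 0`` the filter degenerates to a low-pass.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz >= Nyquist {nyquist} Hz at TR {ts.tr_seconds}s"
        )
    fs = 1.0 / ts.tr_seconds
    if low_hz <= 0:
        sos = sps.butter(2, high_hz, btype="lowpass", fs=fs, output="sos")
    else:
        sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return ts.with_data(sps.sosfiltfilt(sos, ts.data, axis=0))


def preprocess(
    ts: RoiTimeSeries,
    n_discard: int = 10,
    detrend: bool = True,
    band: tuple | None = (0.01, 0.08),
) -> RoiTimeSeries:
    """Fixed-order temporal pipeline: discard -> detrend -> band-pass.

    Each stage can be disabled (``n_discard=0``, ``detrend=False``,
    ``band=None``) but the order cannot be changed.
    """
    out = discard_initial(ts, n_discard)
    if detrend:
        out = detrend_linear(out)
    if band is not None:
        out = bandpass(out, band[0], band[1])
    return out
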