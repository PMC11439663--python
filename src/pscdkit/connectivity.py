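"""Functional connectivity from region-level BOLD time series.

Functional connectivity (FC) here is the Pearson correlation between the
spatially averaged BOLD signals of two brain regions.  The resulting
region x region matrix, optionally Fisher z-transformed (atanh), is the
input to density thresholding, graph attributes and system segregation.

Preprocessing (motion correction, filtering, global-signal handling) is
assumed to have happened upstream; this module starts from clean
region-level time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BoldTimeSeries",
    "ConnectivityMatrix",
    "compute_fc",
    "fisher_z",
    "read_bold",
    "read_matrix",
    "write_matrix",
]

#: |r| is clipped at 1 - R_CLIP before atanh so duplicated regions cannot
#: inject infinities into downstream means.
R_CLIP = 1e-7


@dataclass
class BoldTimeSeries:
    """Time x node matrix of region-averaged BOLD signals."""

    values: np.ndarray
    node_labels: list[str]
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be a 2-D time x node matrix")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 nodes")
        if len(self.node_labels) != self.values.shape[1]:
            raise ValueError("node_labels length does not match node count")
        if not np.isfinite(self.values).all():
            raise ValueError("BOLD values contain missing/non-finite entries")
        if self.tr_seconds is not None and self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node connectivity, Pearson r or Fisher z.

    On the ``fisher_z`` scale the diagonal is stored as 0 and excluded from
    every aggregate by convention.
    """

    values: np.ndarray
    node_labels: list[str]
    scale: str = "pearson_r"  # or "fisher_z"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match matrix size")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix is not symmetric")
        if self.scale == "pearson_r":
            if np.nanmax(np.abs(self.values)) > 1 + 1e-12:
                raise ValueError("pearson_r entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def compute_fc(ts: BoldTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of node time courses.

    Raises ``ValueError`` naming the offending node if any column has zero
    variance (a correlation is undefined there).
    """
    sd = ts.values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.node_labels[i] for i in bad)
        raise ValueError(f"zero-variance BOLD signal for node(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    # guard tiny numerical excursions outside [-1, 1]
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, list(ts.node_labels), scale="pearson_r")


def fisher_z(c: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z transform, z = atanh(r), with |r| clipped at 1 - 1e-7.

    The diagonal is set to 0; consumers ignore it.
    """
    if c.scale != "pearson_r":
        raise ValueError("input is already Fisher z-transformed")
    r = np.clip(c.values, -1.0 + R_CLIP, 1.0 - R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, list(c.node_labels), scale="fisher_z")


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_bold(path: str | Path, sep: str = "\t", tr_seconds: float | None = None) -> BoldTimeSeries:
    """Read a time x node table whose header row holds the node labels."""
    df = pd.read_csv(path, sep=sep)
    return BoldTimeSeries(df.to_numpy(dtype=float), [str(c) for c in df.columns], tr_seconds)


def write_matrix(c: ConnectivityMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(c.values, index=c.node_labels, columns=c.node_labels)
    df.to_csv(path, sep=sep)


def read_matrix(path: str | Path, scale: str = "pearson_r", sep: str = "\t") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], scale=scale)
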