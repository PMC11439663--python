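"""System segregation of canonical resting-state networks.

For a network module m,

    SysSeg(m) = (Zw - Zb) / Zw

where Zw is the mean Fisher z-transformed connectivity over node pairs
within m and Zb the mean over pairs with one endpoint in m and the other
in any other analysis network.  SysSeg quantifies a module's functional
isolation: 1 means no between-network coupling, 0 means within equals
between.  It operates on the full z matrix (no thresholding).

Pairs with negative z are excluded from both means by default, following
the segregation literature; the behaviour is toggleable.  The seven
cortical canonical networks (VN, SMN, DAN, VAN, LN, FPN, DMN) form the
default analysis set; subcortical/cerebellar/brainstem pools are excluded
from between-network pairs unless requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "CANONICAL_NETWORKS",
    "NON_ANALYSIS_POOLS",
    "CanonicalPartition",
    "SegregationResult",
    "system_segregation",
    "read_partition",
]

#: the seven cortical resting-state systems entering SysSeg by default
CANONICAL_NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")
NON_ANALYSIS_POOLS = ("subcortical", "cerebellum", "brainstem")


@dataclass
class CanonicalPartition:
    """node index -> canonical network label, plus the analysis subset."""

    assignment: dict[int, str]
    analysis_set: tuple[str, ...] = CANONICAL_NETWORKS

    def __post_init__(self) -> None:
        if not self.analysis_set:
            raise ValueError("analysis_set must be nonempty")
        counts: dict[str, int] = {}
        for lbl in self.assignment.values():
            counts[lbl] = counts.get(lbl, 0) + 1
        missing = [m for m in self.analysis_set if counts.get(m, 0) < 2]
        if missing:
            raise ValueError(
                f"analysis network(s) with fewer than 2 nodes: {', '.join(missing)}"
            )

    def labels_array(self, n_nodes: int) -> np.ndarray:
        if set(self.assignment) != set(range(n_nodes)):
            raise ValueError("partition does not label every matrix node exactly once")
        return np.array([self.assignment[i] for i in range(n_nodes)])


@dataclass
class SegregationResult:
    """Per-network and pooled SysSeg with the means behind them.

    Each entry holds ``sysseg`` (None with a ``reason`` when Zw <= 0 or no
    pairs survive exclusion), ``z_within_mean``, ``z_between_mean`` and the
    pair counts after exclusion.
    """

    per_network: dict[str, dict]
    overall: dict

    def to_frame(self, subject: str | None = None) -> pd.DataFrame:
        rows = []
        for net, vals in {**self.per_network, "all": self.overall}.items():
            row = {"network": net, **vals}
            if subject is not None:
                row = {"subject": subject, **row}
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"per_network": self.per_network, "overall": self.overall}, indent=2)
        )


def _mean_stats(z: np.ndarray) -> tuple[float | None, int]:
    if z.size == 0:
        return None, 0
    return float(z.mean()), int(z.size)


def _sysseg_entry(zw: np.ndarray, zb: np.ndarray) -> dict:
    zw_mean, nw = _mean_stats(zw)
    zb_mean, nb = _mean_stats(zb)
    entry = {
        "sysseg": None,
        "z_within_mean": zw_mean,
        "z_between_mean": zb_mean,
        "n_within_pairs": nw,
        "n_between_pairs": nb,
    }
    if zw_mean is None:
        entry["reason"] = "no within-network pairs after exclusion"
    elif zw_mean <= 0:
        entry["reason"] = "non-positive mean within-network connectivity"
    elif zb_mean is None:
        entry["reason"] = "no between-network pairs after exclusion"
    else:
        entry["sysseg"] = (zw_mean - zb_mean) / zw_mean
    return entry


def system_segregation(
    c: ConnectivityMatrix,
    p: CanonicalPartition,
    exclude_negative: bool = True,
    include_non_analysis: bool = False,
    overall_method: str = "pooled",
) -> SegregationResult:
    """SysSeg per analysis network and pooled across the analysis set.

    ``overall_method='pooled'`` (default) computes the overall statistic
    from the pooled within-pairs mean vs the pooled between-pairs mean
    (each unordered cross pair counted once); ``'mean'`` averages the
    per-network sysseg values instead.
    """
    if c.scale != "fisher_z":
        raise ValueError("system segregation requires a fisher_z matrix")
    if overall_method not in ("pooled", "mean"):
        raise ValueError("overall_method must be 'pooled' or 'mean'")
    n = c.n_nodes
    labels = p.labels_array(n)
    iu, ju = np.triu_indices(n, 1)
    z = c.values[iu, ju]
    li, lj = labels[iu], labels[ju]
    in_analysis = np.isin(labels, p.analysis_set)
    ai, aj = in_analysis[iu], in_analysis[ju]
    included = z >= 0 if exclude_negative else np.ones_like(z, dtype=bool)

    per_network: dict[str, dict] = {}
    for m in p.analysis_set:
        wi = (li == m) & (lj == m) & included
        if include_non_analysis:
            partner_ok_i, partner_ok_j = np.ones_like(ai), np.ones_like(aj)
        else:
            partner_ok_i, partner_ok_j = ai, aj
        bi = (
            (((li == m) & (lj != m) & partner_ok_j) | ((lj == m) & (li != m) & partner_ok_i))
            & included
        )
        per_network[m] = _sysseg_entry(z[wi], z[bi])

    within_pool = (li == lj) & ai & included
    cross_pool = (li != lj) & ai & aj & included
    if overall_method == "pooled":
        overall = _sysseg_entry(z[within_pool], z[cross_pool])
    else:
        vals = [e["sysseg"] for e in per_network.values() if e["sysseg"] is not None]
        overall = _sysseg_entry(z[within_pool], z[cross_pool])
        overall["sysseg"] = float(np.mean(vals)) if vals else None
        if not vals:
            overall["reason"] = "no network with a defined sysseg"
    return SegregationResult(per_network, overall)


def read_partition(
    path: str | Path,
    node_labels: list[str] | None = None,
    analysis_set: tuple[str, ...] = CANONICAL_NETWORKS,
    sep: str = "\t",
) -> CanonicalPartition:
    """Read a two-column (node label, network label) table.

    When ``node_labels`` is given, rows are matched to matrix nodes by
    label; otherwise file order defines the node index.
    """
    df = pd.read_csv(path, sep=sep, header=None, names=["node", "network"], dtype=str)
    if node_labels is not None:
        mapping = dict(zip(df["node"], df["network"]))
        missing = [l for l in node_labels if l not in mapping]
        if missing:
            raise ValueError(f"partition file missing nodes: {missing[:5]}")
        assignment = {i: mapping[l] for i, l in enumerate(node_labels)}
    else:
        assignment = dict(enumerate(df["network"]))
    present = set(assignment.values())
    analysis = tuple(m for m in analysis_set if m in present)
    return CanonicalPartition(assignment, analysis or tuple(sorted(present)))
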