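"""Subject-level parameter spaces, clustering and group-difference maps.

Per-subject feature vectors (mode percentages, dip, stride proxy, pelvic
NSR, network asymmetry, forces, timings) are assembled into the parameter
spaces in which cohorts stratify into self-emerging clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .spectral import welch_mean_frequency


@dataclass
class SubjectFeatures:
    """One subject's coordinates across the analysis parameter spaces."""

    subject_id: str
    group_label: str
    mode1_pct: float | None = None
    dip: float | None = None
    speed_over_frequency_m: float | None = None
    pelvic_nsr: float | None = None
    asymmetry_index: float | None = None
    mean_skewness: float | None = None
    mean_force_LR: float | None = None
    mean_force_RL: float | None = None
    mean_timing_s: float | None = None
    nsr: float | None = None
    node_mean_intervals_s: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items()
               if k != "node_mean_intervals_s"}
        for node, val in self.node_mean_intervals_s.items():
            row[f"interval_{node}_s"] = val
        return row


def features_table(features: Sequence[SubjectFeatures]) -> pd.DataFrame:
    return pd.DataFrame([f.to_row() for f in features])


def stride_proxy(
    speed_series: np.ndarray,
    rate_hz: float,
) -> tuple[float, float, float]:
    """Mean speed, mean frequency of the speed series, and their ratio.

    The ratio has units of meters: distance traveled per unit time divided
    by strides per unit time is distance per stride. The spectrum is taken
    on the demeaned speed so the DC term does not absorb the power.
    """
    v = np.asarray(speed_series, dtype=float)
    if len(v) == 0:
        raise ValueError("empty speed series")
    mean_speed = float(v.mean())
    f_mean = welch_mean_frequency(v, rate_hz)
    if f_mean <= 0:
        raise ValueError("zero mean frequency")
    return mean_speed, f_mean, mean_speed / f_mean


def normalize_features(
    table: pd.DataFrame,
    method: str = "minmax",
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Normalize feature columns; returns (table, constant-feature flags).

    ``minmax`` maps each feature to [0, 1]; ``zscore`` standardizes.
    Constant features become all-zero and are flagged rather than divided
    by zero.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 subjects to normalize")
    out = table.copy()
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    flagged = []
    for c in cols:
        x = out[c].astype(float)
        span = x.max() - x.min() if method == "minmax" else x.std(ddof=0)
        if span == 0 or not np.isfinite(span):
            out[c] = 0.0
            flagged.append(c)
        elif method == "minmax":
            out[c] = (x - x.min()) / span
        elif method == "zscore":
            out[c] = (x - x.mean()) / span
        else:
            raise ValueError(f"unknown normalization method {method!r}")
    return out, flagged


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    silhouette: float | None


def cluster_subjects(
    features: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Euclidean k-means with seeded restarts; deterministic under a seed."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if k > n:
        raise ValueError(f"k={k} exceeds number of subjects n={n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    sil = None
    if 1 < k < n and len(np.unique(labels)) > 1:
        sil = float(silhouette_score(x, labels))
    return ClusterResult(k=k, assignments=labels, centroids=km.cluster_centers_,
                         inertia=float(km.inertia_), silhouette=sil)


def suggest_k(features: np.ndarray, k_range=range(2, 6), seed: int = 0) -> int:
    """Silhouette scan helper; advisory only, never overrides a configured k."""
    x = np.asarray(features, dtype=float)
    best_k, best_s = 2, -np.inf
    for k in k_range:
        if k >= len(x):
            break
        res = cluster_subjects(x, k, seed=seed)
        if res.silhouette is not None and res.silhouette > best_s:
            best_k, best_s = k, res.silhouette
    return best_k


def group_difference_map(
    group_a: Mapping[str, Sequence[float]] | pd.DataFrame,
    group_b: Mapping[str, Sequence[float]] | pd.DataFrame,
    alpha: float = 0.05,
    *,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-node signed mean differences, zeroed where not significant.

    Welch two-sample t-test per node; the entry is mean(A) - mean(B) when
    p < alpha, else 0. An optional Benjamini-Hochberg correction across
    nodes is off by default.
    """
    a = pd.DataFrame(group_a)
    b = pd.DataFrame(group_b)
    nodes = [c for c in a.columns if c in b.columns]
    if not nodes:
        raise ValueError("no shared nodes between groups")
    rows = []
    pvals = []
    for node in nodes:
        xa = np.asarray(a[node].dropna(), dtype=float)
        xb = np.asarray(b[node].dropna(), dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group with < 2 subjects for node {node!r}")
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append((node, float(xa.mean() - xb.mean()), float(p)))
        pvals.append(p)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        sig = dict(zip(nodes, reject))
    else:
        sig = {node: p < alpha for node, _, p in rows}
    return pd.DataFrame(
        {"node": [r[0] for r in rows],
         "difference": [r[1] if sig[r[0]] else 0.0 for r in rows],
         "p_value": [r[2] for r in rows]}
    ).set_index("node")


def centroid_summary(
    table: pd.DataFrame,
    feature_columns: Sequence[str],
    group_column: str = "group_label",
) -> pd.DataFrame:
    """Per-group mean point in the chosen feature space."""
    if table.empty:
        raise ValueError("empty feature table")
    grouped = table.groupby(group_column)[list(feature_columns)].mean()
    if (table.groupby(group_column).size() == 0).any():
        raise ValueError("empty group")
    return grouped
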