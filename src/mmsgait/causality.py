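"""Single-internal-delay Granger causality on MMS spike series.

The model compares a non-causal one-tap autoregression of the target,

    x_n = a1 * x_{n-l} + w1_n,

with a causal model that adds one lagged tap of the candidate source,

    x_n = a2 * x_{n-l} + b * y_{n-l} + w2_n,

for a single internal delay l (by default in spike-index units: one lag is
one inter-peak step). Causality is the log ratio of the two noise
variances, GC = log(sigma1^2 / sigma2^2); GC > 0 means the source improves
the prediction. Sweeping l and taking the argmax gives the "internal motor
timing" of the pair; force = max GC / optimal lag is a proxy for the speed
of information transfer.

Two estimator modes are provided. ``paper`` solves the classical
pencil-and-paper moment equations in closed form: a1 = Rxx(0)/Rxx(l); the
2x2 system
Rxx(0) = a2 Rxx(l) + b Rxy(l), Rxx(l) = a2 Rxx(0) + b Rxy(0);
sigma1^2 = (1 - a1^2) Rxx(0);
sigma2^2 = (1 - a2^2) Rxx(0) - b^2 Ryy(0) - 2 a2 b Rxy(0).
Those moment equations drop noise-process cross terms that are nonzero
under the generative model, so the sigmas can go negative: the ``strict``
validity policy marks such lags invalid; ``permissive`` keeps the GC
whenever the variance ratio is positive. ``ols`` mode solves the standard
least-squares normal equations instead, whose residual variances are
nonnegative by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

EstimatorMode = Literal["paper", "ols"]
ValidityPolicy = Literal["strict", "permissive"]

_SINGULAR_RTOL = 1e-12


@dataclass
class CovarianceSet:
    """Sample moments of a centered pair (x, y) at one candidate lag.

    The primary fields use the 1/(n - tau) convention over aligned
    samples. ``aligned`` optionally carries the Gram-consistent moments
    (every expectation over the same index set t in [lag, n)), which make
    the least-squares residual variance an exact projection and hence
    nonnegative; :func:`sample_moments` fills them in.
    """

    Rxx0: float
    Rxxl: float
    Ryy0: float
    Rxy0: float
    Rxyl: float
    lag: int = 0
    aligned: tuple[float, float, float, float, float, float] | None = None
    # aligned = (gxx, gxy, gyy, rx, ry, target_var)

    def __post_init__(self) -> None:
        if not (self.Rxx0 > 0 and self.Ryy0 > 0):
            raise ValueError("zero-lag autocovariances must be positive")


@dataclass
class GCResult:
    """Model constants, noise variances and GC at one lag."""

    a1: float | None
    a2: float | None
    b: float | None
    sigma1_sq: float | None
    sigma2_sq: float | None
    gc: float | None
    valid: bool
    reason: str = ""


@dataclass
class LagSweep:
    """GC evaluated over a lag grid, with the optimum and derived force."""

    lags: np.ndarray
    gc: np.ndarray                   # nan where invalid
    results: list[GCResult]
    estimator_mode: EstimatorMode
    validity_policy: ValidityPolicy
    optimal_lag: int | None
    max_gc: float | None

    @property
    def force(self) -> float | None:
        if self.max_gc is None or not self.optimal_lag:
            return None
        return self.max_gc / self.optimal_lag

    @property
    def no_valid_lag(self) -> bool:
        return self.optimal_lag is None


def sample_moments(x: np.ndarray, y: np.ndarray, lag: int) -> CovarianceSet:
    """Sample autocovariances / cross-covariances at one lag.

    Series are mean-centered and truncated to common length first.
    R(tau) uses the 1/(n - tau) convention over aligned samples; the
    zero-lag cross moment is symmetric, Rxy(0) = mean(x_t * y_t).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(len(x), len(y))
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if n <= lag + 2:
        raise ValueError(
            f"insufficient samples for lag {lag}: n={n} <= lag + 2")
    x = x[:n] - x[:n].mean()
    y = y[:n] - y[:n].mean()
    xt, xl, yl = x[lag:], x[:-lag], y[:-lag]
    m = n - lag
    aligned = (float(xl @ xl / m), float(xl @ yl / m), float(yl @ yl / m),
               float(xt @ xl / m), float(xt @ yl / m), float(xt @ xt / m))
    return CovarianceSet(
        Rxx0=float(x @ x / n),
        Rxxl=float(xt @ xl / (n - lag)),
        Ryy0=float(y @ y / n),
        Rxy0=float(x @ y / n),
        Rxyl=float(xt @ yl / (n - lag)),
        lag=lag,
        aligned=aligned,
    )


def gc_single_lag(
    cov: CovarianceSet,
    mode: EstimatorMode = "paper",
    policy: ValidityPolicy = "strict",
) -> GCResult:
    """Solve the single-delay model from moments and return GC for one lag."""
    Rxx0, Rxxl, Ryy0, Rxy0, Rxyl = (
        cov.Rxx0, cov.Rxxl, cov.Ryy0, cov.Rxy0, cov.Rxyl)
    scale = max(abs(Rxx0), abs(Ryy0))

    if mode == "paper":
        if Rxxl == 0:
            return GCResult(None, None, None, None, None, None, False,
                            "Rxx(l) = 0: a1 undefined")
        a1 = Rxx0 / Rxxl
        # 2x2 system: [[Rxxl, Rxyl], [Rxx0, Rxy0]] @ [a2, b] = [Rxx0, Rxxl]
        det = Rxxl * Rxy0 - Rxyl * Rxx0
        if abs(det) < _SINGULAR_RTOL * scale ** 2:
            return GCResult(None, None, None, None, None, None, False,
                            "collinear")
        a2 = (Rxx0 * Rxy0 - Rxyl * Rxxl) / det
        b = (Rxxl * Rxxl - Rxx0 * Rxx0) / det
        sigma1 = (1.0 - a1 ** 2) * Rxx0
        sigma2 = (1.0 - a2 ** 2) * Rxx0 - b ** 2 * Ryy0 - 2.0 * a2 * b * Rxy0
    elif mode == "ols":
        if cov.aligned is not None:
            # Gram-consistent moments: the residual variance is an exact
            # least-squares projection, nonnegative by construction
            gxx, gxy, gyy, rx, ry, tvar = cov.aligned
        else:
            gxx, gxy, gyy, rx, ry, tvar = Rxx0, Rxy0, Ryy0, Rxxl, Rxyl, Rxx0
        det = gxx * gyy - gxy ** 2
        if abs(det) < _SINGULAR_RTOL * scale ** 2 or gxx <= 0:
            return GCResult(None, None, None, None, None, None, False,
                            "collinear")
        a1 = rx / gxx
        a2 = (gyy * rx - gxy * ry) / det
        b = (gxx * ry - gxy * rx) / det
        sigma1 = tvar - a1 * rx
        sigma2 = tvar - (a2 * rx + b * ry)
    else:
        raise ValueError(f"unknown estimator mode {mode!r}")

    if policy == "strict":
        if sigma1 <= 0 or sigma2 <= 0:
            return GCResult(a1, a2, b, sigma1, sigma2, None, False,
                            "non-positive noise variance")
    elif policy == "permissive":
        if sigma2 == 0 or sigma1 / sigma2 <= 0:
            return GCResult(a1, a2, b, sigma1, sigma2, None, False,
                            "non-positive variance ratio")
    else:
        raise ValueError(f"unknown validity policy {policy!r}")
    gc = float(np.log(sigma1 / sigma2))
    return GCResult(a1, a2, b, sigma1, sigma2, gc, True)


def lag_sweep(
    x: np.ndarray,
    y: np.ndarray,
    lag_range: Iterable[int] = range(1, 51),
    mode: EstimatorMode = "paper",
    policy: ValidityPolicy = "strict",
) -> LagSweep:
    """Evaluate GC(y -> x) per candidate lag and locate the optimum.

    Lags are capped at n/4. The optimal lag is the smallest lag attaining
    the maximal valid GC; a sweep with no valid lag is flagged rather than
    raised.
    """
    lags = np.asarray(sorted(set(int(l) for l in lag_range)), dtype=int)
    if len(lags) == 0:
        raise ValueError("empty lag range")
    if lags[0] < 1:
        raise ValueError("lags must be positive integers")
    n = min(len(x), len(y))
    lags = lags[lags <= n // 4]
    if len(lags) == 0:
        raise ValueError(f"all lags exceed n/4 = {n // 4}")

    results: list[GCResult] = []
    gc = np.full(len(lags), np.nan)
    for i, lag in enumerate(lags):
        cov = sample_moments(x, y, int(lag))
        res = gc_single_lag(cov, mode=mode, policy=policy)
        results.append(res)
        if res.valid:
            gc[i] = res.gc
    if np.all(np.isnan(gc)):
        optimal, max_gc = None, None
    else:
        i = int(np.nanargmax(gc))        # ties: nanargmax takes the first,
        optimal, max_gc = int(lags[i]), float(gc[i])  # i.e. the smallest lag
    return LagSweep(lags=lags, gc=gc, results=results, estimator_mode=mode,
                    validity_policy=policy, optimal_lag=optimal, max_gc=max_gc)


@dataclass
class SignificanceResult:
    p_value: float
    significant: bool
    observed_max_gc: float | None
    n_surrogates: int


def gc_significance(
    x: np.ndarray,
    y: np.ndarray,
    sweep: LagSweep,
    *,
    alpha: float = 0.01,
    n_surrogates: int = 199,
    seed: int | np.random.Generator = 0,
) -> SignificanceResult:
    """Surrogate test of the sweep's max GC via circular shifts of the source.

    The null is built by circularly shifting y by random offsets and
    recomputing the max GC of the sweep; p = (1 + #{surrogate >=
    observed}) / (1 + B). Offsets keep a circular distance of at least
    twice the maximum candidate lag from zero (an offset of n - 3 is a
    3-sample shift backwards): shifts barely beyond the lag grid let the
    source's serial dependence leak the true coupling into the null, in
    both time directions.
    """
    if n_surrogates < 99:
        raise ValueError("need at least 99 surrogates")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = min(len(x), len(y))
    max_lag = int(sweep.lags.max())
    if n < 4 * max_lag:
        raise ValueError(
            f"series too short for surrogates: n={n} < 4 * max lag {max_lag}")
    if sweep.max_gc is None:
        return SignificanceResult(1.0, False, None, n_surrogates)
    observed = sweep.max_gc
    y = np.asarray(y, dtype=float)[:n]
    x = np.asarray(x, dtype=float)[:n]
    exceed = 0
    margin = min(2 * max_lag, n // 4)
    offsets = rng.integers(margin, n - margin, size=n_surrogates)
    for off in offsets:
        y_s = np.roll(y, int(off))
        s = lag_sweep(x, y_s, sweep.lags, mode=sweep.estimator_mode,
                      policy=sweep.validity_policy)
        if s.max_gc is not None and s.max_gc >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_surrogates)
    return SignificanceResult(float(p), bool(p <= alpha), observed,
                              n_surrogates)


def detect_feedback(
    sweep_ab: LagSweep,
    sweep_ba: LagSweep,
    sig_ab: SignificanceResult,
    sig_ba: SignificanceResult,
) -> bool:
    """A feedback loop exists iff causality is significant both ways
    with positive max GC."""
    def ok(sweep: LagSweep, sig: SignificanceResult) -> bool:
        return (sig.significant and sweep.max_gc is not None
                and sweep.max_gc > 0)
    return ok(sweep_ab, sig_ab) and ok(sweep_ba, sig_ba)


@dataclass
class CausalEdge:
    source: str
    target: str
    max_gc: float | None
    optimal_lag: int | None
    force: float | None
    p_value: float
    significant: bool


@dataclass
class CausalNetwork:
    """Directed GC network over body nodes with per-node summaries."""

    nodes: list[str]
    edges: dict[tuple[str, str], CausalEdge]
    out_degree: dict[str, int] = field(default_factory=dict)
    max_outward_gc: dict[str, float] = field(default_factory=dict)
    max_outward_lag: dict[str, int] = field(default_factory=dict)
    asymmetry_index: float = float("nan")
    feedback_pairs: set[frozenset[str]] = field(default_factory=set)

    def to_graph(self):
        """Export significant edges as a networkx DiGraph."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (s, t), e in self.edges.items():
            if e.significant and e.max_gc is not None:
                g.add_edge(s, t, max_gc=e.max_gc, optimal_lag=e.optimal_lag,
                           force=e.force, p_value=e.p_value)
        return g


def build_network(
    nodes: Sequence[str],
    sweeps: Mapping[tuple[str, str], LagSweep],
    significances: Mapping[tuple[str, str], SignificanceResult],
) -> CausalNetwork:
    """Assemble pairwise sweeps into a directed network with summaries.

    The asymmetry index is the normalized L1 directional difference
    sum_{i<j} |GC(i->j) - GC(j->i)| / sum_{i<j} (GC(i->j) + GC(j->i))
    over pairs where both directions carry a valid positive GC.
    """
    nodes = list(nodes)
    missing = [pair for pair in permutations(nodes, 2) if pair not in sweeps]
    if missing:
        raise ValueError(f"missing pairwise sweeps: {missing}")

    edges: dict[tuple[str, str], CausalEdge] = {}
    for pair in permutations(nodes, 2):
        sw = sweeps[pair]
        sig = significances[pair]
        edges[pair] = CausalEdge(
            source=pair[0], target=pair[1], max_gc=sw.max_gc,
            optimal_lag=sw.optimal_lag, force=sw.force,
            p_value=sig.p_value, significant=sig.significant)

    out_degree = {n: 0 for n in nodes}
    max_gc = {}
    max_lag = {}
    for (s, t), e in edges.items():
        if e.significant:
            out_degree[s] += 1
        if e.max_gc is not None and (s not in max_gc or e.max_gc > max_gc[s]):
            max_gc[s] = e.max_gc
            max_lag[s] = e.optimal_lag
    num = den = 0.0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            g_ab, g_ba = edges[(a, b)].max_gc, edges[(b, a)].max_gc
            if (g_ab is not None and g_ba is not None
                    and g_ab > 0 and g_ba > 0):
                num += abs(g_ab - g_ba)
                den += g_ab + g_ba
    asym = num / den if den > 0 else float("nan")

    feedback: set[frozenset[str]] = set()
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if detect_feedback(sweeps[(a, b)], sweeps[(b, a)],
                               significances[(a, b)], significances[(b, a)]):
                feedback.add(frozenset((a, b)))

    return CausalNetwork(nodes=nodes, edges=edges, out_degree=out_degree,
                         max_outward_gc=max_gc, max_outward_lag=max_lag,
                         asymmetry_index=asym, feedback_pairs=feedback)


def group_feedback_map(networks: Sequence[CausalNetwork]) -> "pd.DataFrame":
    """Percentage of subjects with a feedback loop, per unordered node pair.

    Returns a symmetric node-by-node DataFrame of percentages.
    """
    import pandas as pd

    if not networks:
        raise ValueError("empty group")
    nodes = networks[0].nodes
    for net in networks:
        if net.nodes != nodes:
            raise ValueError("networks do not share a node set")
    mat = np.zeros((len(nodes), len(nodes)))
    for net in networks:
        for pair in net.feedback_pairs:
            a, b = sorted(pair)
            i, j = nodes.index(a), nodes.index(b)
            mat[i, j] += 1
            mat[j, i] += 1
    mat = 100.0 * mat / len(networks)
    return pd.DataFrame(mat, index=nodes, columns=nodes)
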