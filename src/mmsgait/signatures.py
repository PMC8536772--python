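"""Stochastic signatures of MMS fluctuations.

Per subject and signal the package summarizes the distribution of
normalized spike amplitudes by:

* a maximum-likelihood gamma fit whose scale parameter is the
  noise-to-signal ratio (for a gamma variate, variance/mean = scale);
* the adjusted Fisher-Pearson sample skewness;
* Hartigan's dip statistic of unimodality with a bootstrap p-value;
* a two-component decomposition of the amplitude distribution into a
  low-amplitude exponential mode and a higher-amplitude Gaussian mode,
  fitted by expectation-maximization.

The dip statistic is the sup-norm distance between the empirical CDF and
the closest unimodal CDF. It is computed exactly: for each candidate mode
position the best unimodal fit splits into a convex approximation problem
to the left and a concave one to the right, each solved by a greatest
convex minorant / least concave majorant of the CDF's step corners; the
dip is half the smallest achievable max of the two one-sided errors. Both
one-sided errors are monotone in the split position, so the optimum is
found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StochasticSignature", "gamma_signature", "dip_statistic", "dip_test",
    "ModeDecomposition", "mode_decompose", "amplitude_timing_hist2d",
    "compute_signature",
]


@dataclass
class StochasticSignature:
    """Per-signal feature bundle used for subject stratification."""

    gamma_shape: float
    gamma_scale: float          # = noise-to-signal ratio (NSR)
    skewness: float
    dip_statistic: float
    dip_p: float
    mode1_fraction: float       # exponential-mode share of points
    mode2_fraction: float
    mode1_rate: float
    mode2_mean: float
    mode2_sd: float
    dominant_mode: str          # "exponential" or "gaussian"

    @property
    def nsr(self) -> float:
        return self.gamma_scale


def gamma_signature(values: np.ndarray) -> tuple[float, float, float]:
    """MLE gamma fit (location pinned at 0) plus sample skewness.

    Returns (shape, scale, skewness); the scale is the NSR. Requires at
    least 20 strictly positive values.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 20:
        raise ValueError(f"need at least 20 values for a gamma fit, got {len(v)}")
    if np.any(v <= 0):
        raise ValueError("gamma fit requires strictly positive values")
    shape, _, scale = stats.gamma.fit(v, floc=0)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise ValueError("gamma MLE did not converge")
    skew = float(stats.skew(v, bias=False))
    return float(shape), float(scale), skew


# ---------------------------------------------------------------------------
# Hartigan dip
# ---------------------------------------------------------------------------

def _one_sided_errors(xu: np.ndarray, lo: np.ndarray, up: np.ndarray
                      ) -> np.ndarray:
    """Convex-side approximation error (twice the sup distance) per mode.

    For mode at block m, the best nondecreasing convex CDF piece left of
    the mode must run below the ECDF left limits (lo) of blocks <= m and
    above the ECDF values (up) of blocks < m. Its error is how far the up
    corners poke above the greatest convex minorant of the lo corners.
    Computed for all m in one amortized hull sweep.
    """
    nb = len(xu)
    out = np.empty(nb)
    hx: list[float] = []
    hy: list[float] = []
    run_max = 0.0
    for m in range(nb):
        x, y = xu[m], lo[m]
        lo_span = m
        while len(hx) >= 2 and (
                (hy[-1] - hy[-2]) * (x - hx[-1])
                >= (y - hy[-1]) * (hx[-1] - hx[-2])):
            hx.pop()
            hy.pop()
            lo_span -= 1
        # the new terminal edge replaces the hull over (hx[-1], x]; the
        # hull only moves down there, so deviations only grow
        if hx:
            j0 = int(np.searchsorted(xu, hx[-1], side="right"))
            if j0 < m:
                seg = hy[-1] + (y - hy[-1]) * (xu[j0:m] - hx[-1]) / (x - hx[-1])
                run_max = max(run_max, float(np.max(up[j0:m] - seg)))
        hx.append(x)
        hy.append(y)
        out[m] = run_max
        run_max = max(run_max, up[m] - lo[m])   # own tie mass, for later m
    return out


def _slope_matrices(xu, lo, up):
    """Pairwise forced-slope ingredients shared by both junction sides.

    Entry (k, j), j < k, holds (up_k - lo_j) / (x_k - x_j) and its
    1/(x_k - x_j) companion, so that the forced wedge slope at a corner is
    max over the row (convex side, k as target) or over the column
    (concave side, k as source) of M1 - 2d * M2.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        dx = xu[:, None] - xu[None, :]
        m1 = (up[:, None] - lo[None, :]) / dx
        m2 = 1.0 / dx
    mask = np.tril(np.ones((len(xu), len(xu)), dtype=bool), -1)
    return np.where(mask, m1, -np.inf), np.where(mask, m2, 0.0)


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan's dip: sup-distance from the ECDF to the nearest unimodal CDF.

    The minimization runs over candidate mode blocks (the optimal unimodal
    CDF may carry an atom at its mode, which relaxes that block's
    constraints). For each mode the one-sided convex/concave approximation
    errors give a lower bound; where the two sides' reachable values at
    the mode fail to order (pre-atom below post-atom), the exact threshold
    is found by bisection. Lies in [0, 0.25]: 0.25 in the limit of two
    equal point masses, 1/(2n) for a unimodal-compatible sample of n
    distinct points.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2:
        return 0.0
    xu, first = np.unique(v, return_index=True)
    counts = np.diff(np.append(first, n))
    lo = first / n                      # ECDF left limits at each block
    up = (first + counts) / n           # ECDF values at each block
    nb = len(xu)
    if nb == 1:
        return 0.0

    cl = _one_sided_errors(xu, lo, up)
    cr = _one_sided_errors(-xu[::-1], 1.0 - up[::-1], 1.0 - lo[::-1])[::-1]
    d0 = np.maximum(cl, cr) / 2.0
    m1, m2 = _slope_matrices(xu, lo, up)
    before = np.triu(np.ones((nb, nb), dtype=bool), 1)   # rows k < cols m
    after = before.T

    def any_feasible(d: float) -> bool:
        """Is some mode block's junction orderable at tube half-width d?"""
        modes = d0 <= d + 1e-15
        if not modes.any():
            return False
        forced = m1 - (2.0 * d) * m2
        s_left = np.maximum(forced.max(axis=1), 0.0)
        s_right = np.maximum(forced.max(axis=0), 0.0)
        wedge_l = (up - d - s_left * xu)[:, None] + np.outer(s_left, xu)
        vmin = np.where(before, wedge_l, -np.inf).max(axis=0)
        v_pre = np.maximum(np.maximum(vmin, lo - d), 0.0)
        wedge_r = (lo + d - s_right * xu)[:, None] + np.outer(s_right, xu)
        vmax = np.where(after, wedge_r, np.inf).min(axis=0)
        v_post = np.minimum(np.minimum(vmax, up + d), 1.0)
        return bool(np.any(modes & (v_pre <= v_post + 1e-15)))

    lo_d = float(d0.min())
    if any_feasible(lo_d):
        return lo_d
    hi = max(0.26, 2.0 * lo_d)
    while not any_feasible(hi) and hi < 2.0:
        hi *= 2.0
    while hi - lo_d > 1e-12:
        mid = 0.5 * (lo_d + hi)
        if any_feasible(mid):
            hi = mid
        else:
            lo_d = mid
    return float(hi)


def dip_test(
    values: np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    *,
    null_dips: np.ndarray | None = None,
) -> tuple[float, float]:
    """Dip statistic with a bootstrap p-value under the uniform null.

    The null distribution is built from uniform samples of the same size
    (Hartigan's calibration); a precomputed ``null_dips`` table for this n
    may be supplied to amortize repeated tests.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 4:
        raise ValueError("dip test needs at least 4 values")
    d = dip_statistic(v)
    if null_dips is None:
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        null_dips = dip_null_table(n, n_boot, rng)
    p = (1 + int(np.sum(null_dips >= d))) / (1 + len(null_dips))
    return float(d), float(p)


def dip_null_table(n: int, n_boot: int,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Bootstrap table of dip statistics of uniform(0,1) samples of size n."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


# ---------------------------------------------------------------------------
# exponential + Gaussian mode decomposition
# ---------------------------------------------------------------------------

@dataclass
class ModeDecomposition:
    mode1_fraction: float        # share of points assigned to the exponential
    mode1_rate: float
    mode2_mean: float
    mode2_sd: float
    weight1: float               # mixture weight of the exponential mode
    responsibilities: np.ndarray  # (n, 2), rows sum to 1
    assignments: np.ndarray       # 0 = exponential, 1 = gaussian
    dominant_mode: str
    log_likelihood: float
    ll_trace: np.ndarray
    effectively_unimodal: bool
    shift: float                  # exponential support anchor (sample min)


def mode_decompose(
    values: np.ndarray,
    seed: int | np.random.Generator = 0,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    weight_floor: float = 0.1,
) -> ModeDecomposition:
    """EM fit of a two-mode mixture: exponential (low amplitudes) + Gaussian.

    The exponential component's support is anchored at the sample minimum.
    Points are assigned by maximum posterior responsibility;
    ``mode1_fraction`` is the assigned share of the exponential mode and
    the dominant mode is whichever holds more points. A mixture weight
    pinned below ``weight_floor`` (or above 1 - floor) flags the data as
    effectively unimodal.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 50:
        raise ValueError(f"need at least 50 values, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    shift = float(v.min())
    u = v - shift

    # deterministic moment-based init: low third of the range seeds the
    # exponential mode; a small seeded jitter breaks exact-tie degeneracy
    thresh = np.quantile(u, 0.3)
    low = u <= thresh
    if low.sum() < 2 or (~low).sum() < 2:
        low = u <= np.median(u)
    pi1 = float(low.mean())
    rate = 1.0 / max(u[low].mean(), 1e-12)
    mu = float(v[~low].mean())
    sd = float(max(v[~low].std(), 1e-6 * (1 + abs(mu))))
    pi1 = min(max(pi1 + rng.normal(0, 1e-3), 1e-3), 1 - 1e-3)

    ll_trace = []
    ll_prev = -np.inf
    eps = 1e-300
    for _ in range(max_iter):
        # E step
        log_f1 = np.where(u >= 0, np.log(rate) - rate * u, -np.inf)
        log_f2 = stats.norm.logpdf(v, mu, sd)
        a = np.log(pi1 + eps) + log_f1
        b = np.log(1 - pi1 + eps) + log_f2
        m = np.maximum(a, b)
        ll = float(np.sum(m + np.log(np.exp(a - m) + np.exp(b - m))))
        ll_trace.append(ll)
        r1 = np.exp(a - m) / (np.exp(a - m) + np.exp(b - m))
        # M step
        w1 = r1.sum()
        w2 = n - w1
        pi1 = w1 / n
        if w1 > 1e-8:
            rate = w1 / max(np.sum(r1 * u), 1e-300)
        if w2 > 1e-8:
            mu = float(np.sum((1 - r1) * v) / w2)
            sd = float(np.sqrt(max(np.sum((1 - r1) * (v - mu) ** 2) / w2,
                                   1e-12)))
        if ll - ll_prev < tol * (1 + abs(ll)) and ll >= ll_prev - 1e-9:
            ll_prev = ll
            break
        ll_prev = ll
    else:
        if len(ll_trace) >= 2 and ll_trace[-1] < ll_trace[-2] - 1e-6:
            raise RuntimeError(
                f"EM did not converge after {max_iter} iterations; "
                f"log-likelihood trace tail: {ll_trace[-5:]}")

    resp = np.column_stack([r1, 1 - r1])
    assignments = (resp[:, 1] > resp[:, 0]).astype(int)
    frac1 = float(np.mean(assignments == 0))
    unimodal = pi1 < weight_floor or pi1 > 1 - weight_floor
    return ModeDecomposition(
        mode1_fraction=frac1,
        mode1_rate=float(rate),
        mode2_mean=float(mu),
        mode2_sd=float(sd),
        weight1=float(pi1),
        responsibilities=resp,
        assignments=assignments,
        dominant_mode="exponential" if frac1 >= 0.5 else "gaussian",
        log_likelihood=float(ll_trace[-1]),
        ll_trace=np.asarray(ll_trace),
        effectively_unimodal=bool(unimodal),
        shift=shift,
    )


def amplitude_timing_hist2d(
    mms_series,
    bins: int | tuple[int, int] = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Joint histogram of spike amplitude vs preceding inter-peak interval.

    Returns (counts, amp_edges, interval_edges, diagnostic) where the
    diagnostic is a chi-square test of independence on the binned table
    (reported for exploration only, not as a formal inference).
    """
    if len(mms_series) < 2:
        raise ValueError("need at least 2 peaks")
    amps = mms_series.values[1:]
    intervals = mms_series.inter_peak_intervals_s
    counts, ae, ie = np.histogram2d(amps, intervals, bins=bins)
    # chi-square on the table, dropping empty rows/cols to keep it defined
    table = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if table.shape[0] > 1 and table.shape[1] > 1:
        chi2, p, dof, _ = stats.chi2_contingency(table)
    else:
        chi2, p, dof = 0.0, 1.0, 0
    diag = {"chi2": float(chi2), "p_value": float(p), "dof": int(dof),
            "n": int(counts.sum())}
    return counts, ae, ie, diag


def compute_signature(
    values: np.ndarray,
    *,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> StochasticSignature:
    """Full stochastic signature of a set of positive MMS amplitudes."""
    shape, scale, skew = gamma_signature(values)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    dip, dip_p = dip_test(values, n_boot=n_boot, seed=rng)
    modes = mode_decompose(values, seed=rng)
    return StochasticSignature(
        gamma_shape=shape, gamma_scale=scale, skewness=skew,
        dip_statistic=dip, dip_p=dip_p,
        mode1_fraction=modes.mode1_fraction,
        mode2_fraction=1.0 - modes.mode1_fraction,
        mode1_rate=modes.mode1_rate, mode2_mean=modes.mode2_mean,
        mode2_sd=modes.mode2_sd, dominant_mode=modes.dominant_mode,
    )
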