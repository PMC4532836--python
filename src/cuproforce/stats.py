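"""Pathway-partition statistics.

Provides Hartigan's dip statistic for unimodality with Monte-Carlo
(simulation-based) p-values, pathway-fraction estimates with Wilson
confidence intervals, and per-mode "mean +/- sd, n" summaries of
intermediate positions, mirroring the reporting style of force-spectroscopy
studies.

The dip statistic D of an empirical CDF F_n is the smallest sup-norm
distance from F_n to any unimodal CDF,

    D = min_{G unimodal} sup_x | F_n(x) - G(x) |.

It is computed here exactly, via the band formulation: for a candidate mode
position (in a gap between data values, or an atom at a data value), a
unimodal CDF within sup-distance t of F_n exists iff the greatest convex
minorant of the upper CDF limits stays within 2t of the lower limits on the
convex side, and symmetrically (least concave majorant) on the concave
side.  Minimising over mode positions -- t is monotone in the mode index on
each side, so a binary search suffices -- yields D.  Both deviations are
evaluated against the data coordinates, which makes D invariant under
affine transforms of the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DipTestResult",
    "PartitionSummary",
    "dip_statistic",
    "dip_pvalue",
    "dip_null_table",
    "partition_fractions",
    "summarize_modes",
    "gaussian_mixture_crosscheck",
    "PATHWAY_LABELS",
]

#: Canonical unfolding-pathway labels, in reporting order.
PATHWAY_LABELS = ("two-state", "C-first", "N-first", "four-state")


# ---------------------------------------------------------------------------
# Dip statistic
# ---------------------------------------------------------------------------

def _lower_hull_values(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Greatest convex minorant of the points (x, y), evaluated at every x."""
    n = len(x)
    if n <= 2:
        return y.copy()
    stack = [0, 1]
    for i in range(2, n):
        while len(stack) >= 2:
            j, k = stack[-2], stack[-1]
            # pop k if it lies on or above the chord j -> i
            if (y[k] - y[j]) * (x[i] - x[k]) >= (y[i] - y[k]) * (x[k] - x[j]):
                stack.pop()
            else:
                break
        stack.append(i)
    hx = x[stack]
    hy = y[stack]
    return np.interp(x, hx, hy)


def _upper_hull_values(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least concave majorant of the points (x, y), evaluated at every x."""
    return -_lower_hull_values(x, -y)


class _DipWorkspace:
    """Unique values and CDF limits of a sorted sample."""

    def __init__(self, sample: np.ndarray):
        u, counts = np.unique(sample, return_counts=True)
        n = sample.size
        cum = np.cumsum(counts)
        self.u = u
        #: F_n at each unique value (right limit)
        self.a = cum / n
        #: F_n just below each unique value (left limit)
        self.b = (cum - counts) / n
        self.K = len(u)

    def t_sides(self, i: int) -> tuple[float, float]:
        """Half sup-deviations (left convex, right concave) for mode case i.

        Cases are indexed 0..2K: even i = 2m places the mode in the gap
        after the m-th unique value (m = 0 before all data); odd i = 2j - 1
        puts an atom of G at the j-th unique value.
        """
        u, a, b, K = self.u, self.a, self.b, self.K
        if i % 2 == 0:
            m = i // 2
            # convex side covers points 1..m, concave side m+1..K
            if m == 0:
                tl = 0.0
            else:
                hull = _lower_hull_values(u[:m], b[:m])
                tl = float(np.max(a[:m] - hull)) / 2.0
            if m == K:
                tr = 0.0
            else:
                hull = _upper_hull_values(u[m:], a[m:])
                tr = float(np.max(hull - b[m:])) / 2.0
        else:
            j = (i + 1) // 2  # 1-based index of the atom
            # convex side: ends at the atom's left limit (u_j, b_j); the
            # lower hull includes that point, whose own deviation is
            # measured against b_j rather than a_j.
            if j == 1:
                tl = 0.0
            else:
                hull = _lower_hull_values(u[:j], b[:j])
                dev = max(float(np.max(a[: j - 1] - hull[:-1])), b[j - 1] - hull[-1])
                tl = dev / 2.0
            # concave side: starts at the atom's right limit (u_j, a_j)
            if j == K:
                tr = 0.0
            else:
                hull = _upper_hull_values(u[j - 1 :], a[j - 1 :])
                dev = max(float(np.max(hull[1:] - b[j:])), hull[0] - a[j - 1])
                tr = dev / 2.0
        return tl, tr


def _dip_exhaustive(ws: _DipWorkspace) -> float:
    return min(max(ws.t_sides(i)) for i in range(2 * ws.K + 1))


def _dip_search(ws: _DipWorkspace) -> float:
    # tl is nondecreasing and tr nonincreasing in i, so the minimum of
    # max(tl, tr) sits at the first i with tl >= tr.
    lo, hi = 0, 2 * ws.K
    tl_lo, tr_lo = ws.t_sides(lo)
    if tl_lo >= tr_lo:
        return max(tl_lo, tr_lo)
    tl_hi, tr_hi = ws.t_sides(hi)
    if tl_hi < tr_hi:  # pragma: no cover - tr(2K) = 0 makes this unreachable
        return max(tl_hi, tr_hi)
    # invariant: tl(lo) < tr(lo), tl(hi) >= tr(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        tl, tr = ws.t_sides(mid)
        if tl >= tr:
            hi, tl_hi, tr_hi = mid, tl, tr
        else:
            lo, tl_lo, tr_lo = mid, tl, tr
    return min(max(tl_lo, tr_lo), max(tl_hi, tr_hi))


def dip_statistic(sample) -> float:
    """Hartigan's dip statistic of a sample.

    Parameters
    ----------
    sample : array_like
        Real values, n >= 4 (need not be pre-sorted).

    Returns
    -------
    float
        The dip D, in [1/(2n), 0.25] for samples with at least two distinct
        values; 0 for a degenerate point mass.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size < 4:
        raise ValueError(f"dip statistic requires n >= 4, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    return _dip_search(_DipWorkspace(x))


@dataclass(frozen=True)
class DipTestResult:
    """Dip test with a simulation-based p-value against the uniform null."""

    dip: float
    pvalue: float
    n: int
    n_null: int
    seed: int | None

    @property
    def certainty(self) -> float:
        """(1 - p) as a percentage, the customary 'certainty' figure."""
        return (1.0 - self.pvalue) * 100.0


def dip_null_table(n: int, n_null: int, rng: np.random.Generator) -> np.ndarray:
    """Dip statistics of ``n_null`` Uniform(0,1) samples of size ``n``."""
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_null)])


def dip_pvalue(
    sample,
    n_null: int = 10_000,
    seed: int | None = None,
    null_dips: np.ndarray | None = None,
) -> DipTestResult:
    """Monte-Carlo dip test against the Uniform(0,1) null at matching n.

    The p-value uses the (k+1)/(N+1) estimator (k = null exceedances), which
    never returns exactly zero.  A precomputed ``null_dips`` table (from
    :func:`dip_null_table`) may be supplied to amortise the null simulation
    over repeated tests at the same n.

    Parameters
    ----------
    sample : array_like
        Data, n >= 4.
    n_null : int
        Number of uniform null replicates; must be >= 1000 when the table is
        generated here.
    seed : int, optional
        Seed for the null-replicate RNG.
    null_dips : ndarray, optional
        Precomputed null dip statistics (overrides ``n_null``/``seed``).
    """
    x = np.asarray(sample, dtype=float)
    d = dip_statistic(x)
    if null_dips is None:
        if n_null < 1000:
            raise ValueError("n_null must be >= 1000")
        rng = np.random.default_rng(seed)
        null_dips = dip_null_table(x.size, n_null, rng)
    null_dips = np.asarray(null_dips, dtype=float)
    k = int(np.sum(null_dips >= d))
    p = (k + 1) / (null_dips.size + 1)
    return DipTestResult(dip=d, pvalue=p, n=int(x.size), n_null=int(null_dips.size), seed=seed)


# ---------------------------------------------------------------------------
# Pathway fractions and mode summaries
# ---------------------------------------------------------------------------

@dataclass
class PartitionSummary:
    """Counts, fractions and Wilson 95% intervals per pathway label."""

    counts: dict[str, int]
    fractions: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    n: int
    modes: dict[str, dict] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": dict(self.counts),
            "fractions": dict(self.fractions),
            "wilson_95": {k: list(v) for k, v in self.intervals.items()},
            "modes": dict(self.modes),
        }


def partition_fractions(labels) -> PartitionSummary:
    """Pathway-label composition with binomial uncertainty.

    Parameters
    ----------
    labels : sequence of str
        One pathway label per unfolding event/trajectory (non-empty).

    Returns
    -------
    PartitionSummary
        Counts, fractions (summing to 1) and Wilson 95% confidence
        intervals for every canonical label plus any extra labels present.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    n = len(labels)
    keys = list(PATHWAY_LABELS) + sorted(
        {lab for lab in labels if lab not in PATHWAY_LABELS}
    )
    counts = {k: 0 for k in keys}
    for lab in labels:
        counts[lab] += 1
    fractions = {k: counts[k] / n for k in keys}
    intervals = {}
    for k in keys:
        lo, hi = proportion_confint(counts[k], n, alpha=0.05, method="wilson")
        intervals[k] = (float(lo), float(hi))
    return PartitionSummary(counts=counts, fractions=fractions, intervals=intervals, n=n)


def summarize_modes(values, windows: dict[str, tuple[float, float]]) -> dict:
    """Bin intermediate positions into mode windows; report mean +/- sd, n.

    Parameters
    ----------
    values : array_like
        Intermediate positions, nm.
    windows : dict
        label -> (lo, hi) half-open intervals [lo, hi); must be disjoint.

    Returns
    -------
    dict
        label -> {"mean", "sd", "n"} plus an "unassigned" entry with the
        count and values outside every window.
    """
    items = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (_, (lo1, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
        if hi1 > lo2:
            raise ValueError("mode windows must be disjoint")
    vals = np.asarray(values, dtype=float)
    out: dict[str, dict] = {}
    assigned = np.zeros(vals.shape, dtype=bool)
    for label, (lo, hi) in items:
        mask = (vals >= lo) & (vals < hi)
        assigned |= mask
        sel = vals[mask]
        out[label] = {
            "mean": float(np.mean(sel)) if sel.size else float("nan"),
            "sd": float(np.std(sel, ddof=1)) if sel.size > 1 else float("nan"),
            "n": int(sel.size),
        }
    leftover = vals[~assigned]
    out["unassigned"] = {"n": int(leftover.size), "values": leftover.tolist()}
    return out


def gaussian_mixture_crosscheck(
    values, init_means: tuple[float, float], tol: float = 1e-8, seed: int = 0
) -> dict:
    """Two-component Gaussian-mixture cross-check of the window binning.

    Deterministic: initialised at the supplied means (typically the window
    midpoints) rather than randomly.  Returns component means, sds and
    weights sorted by mean.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        means_init=np.asarray(init_means, dtype=float).reshape(-1, 1),
        tol=tol,
        max_iter=10_000,
        random_state=seed,
    ).fit(x)
    order = np.argsort(gm.means_.ravel())
    return {
        "means": gm.means_.ravel()[order].tolist(),
        "sds": np.sqrt(gm.covariances_.ravel()[order]).tolist(),
        "weights": gm.weights_[order].tolist(),
        "converged": bool(gm.converged_),
    }
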