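"""Cohort characterization and between-group statistics.

Islets are characterized by beta-cell fraction and ln(1 + total cell count);
2D distributions are compared by KL divergence between Gaussian kernel
density estimates on a shared 100x100 grid, by a two-sample two-dimensional
Kolmogorov-Smirnov test (Fasano-Franceschini quadrant statistic), and 1D
persistence distributions by the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datamodel import IsletSection


@dataclass(frozen=True)
class IsletCharacteristics:
    beta_fraction: float
    log_total: float
    n_alpha: int
    n_delta: int


@dataclass
class KDEGrid:
    """Gaussian-KDE densities on a regular grid over (x, y) ranges."""

    grid: np.ndarray  # (resolution, resolution), rows = y, cols = x
    x: np.ndarray
    y: np.ndarray
    bandwidth_rule: str = "scott"

    @property
    def resolution(self) -> int:
        return self.grid.shape[0]

    @property
    def ranges(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (
            (float(self.x[0]), float(self.x[-1])),
            (float(self.y[0]), float(self.y[-1])),
        )

    def peak(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.grid), self.grid.shape)
        return float(self.x[ix]), float(self.y[iy])


def characterize(islet: IsletSection) -> IsletCharacteristics:
    """Beta-cell fraction and ln(1 + total cell count) of one islet."""
    n_beta = islet.n_beta
    n_alpha = islet.count("alpha")
    n_delta = islet.count("delta")
    total = n_beta + n_alpha + n_delta
    if total == 0:
        raise ValueError("islet has no cells")
    return IsletCharacteristics(
        beta_fraction=n_beta / total,
        log_total=math.log1p(total),
        n_alpha=n_alpha,
        n_delta=n_delta,
    )


def kde2d(
    sample: np.ndarray,
    resolution: int = 100,
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> KDEGrid:
    """Gaussian product-kernel density (Scott's-rule bandwidth) evaluated on
    a ``resolution`` x ``resolution`` grid."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    if sample.shape[0] < 3:
        raise ValueError("kde2d needs at least three points")
    if ranges is None:
        ranges = default_ranges([sample])
    try:
        kde = sps.gaussian_kde(sample.T, bw_method="scott")
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "degenerate sample covariance; jitter the points slightly"
        ) from e
    (x0, x1), (y0, y1) = ranges
    x = np.linspace(x0, x1, resolution)
    y = np.linspace(y0, y1, resolution)
    xx, yy = np.meshgrid(x, y)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(resolution, resolution)
    return KDEGrid(grid=dens, x=x, y=y)


def default_ranges(samples) -> tuple[tuple[float, float], tuple[float, float]]:
    """Shared grid ranges: min/max over the union of samples, expanded by a
    5% margin on each axis so compared KDEs live on an identical grid."""
    allpts = np.vstack([np.atleast_2d(s) for s in samples])
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    margin = 0.05 * np.where(hi > lo, hi - lo, 1.0)
    lo, hi = lo - margin, hi + margin
    return (float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))


def kl_divergence(P: KDEGrid, Q: KDEGrid) -> float:
    """KL(P || Q) between two density grids on the same ranges/resolution.

    Grids are floored at machine-epsilon-scaled mass and normalized to sum 1
    before sum(p * ln(p/q)); KL(P, P) = 0 and KL >= 0.
    """
    if P.grid.shape != Q.grid.shape or P.ranges != Q.ranges:
        raise ValueError("KDE grids must share resolution and ranges")

    def _norm(g):
        g = np.clip(np.asarray(g, dtype=float), 0, None)
        top = g.max()
        if top <= 0:
            raise ValueError("all-zero density grid")
        g = g + np.finfo(float).eps * top
        return (g / g.sum()).ravel()

    return float(sps.entropy(_norm(P.grid), _norm(Q.grid)))


def _quadrant_fractions(points: np.ndarray, origin: np.ndarray) -> np.ndarray:
    dx = points[:, 0] > origin[0]
    dy = points[:, 1] > origin[1]
    n = len(points)
    return (
        np.array(
            [
                np.sum(dx & dy),
                np.sum(~dx & dy),
                np.sum(~dx & ~dy),
                np.sum(dx & ~dy),
            ]
        )
        / n
    )


def ks2d(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample 2D Kolmogorov-Smirnov test (Fasano-Franceschini).

    The statistic is the largest quadrant-probability difference over the
    points of both samples (averaged between the two sweeps); the p-value
    uses the standard asymptotic Kolmogorov approximation with the
    correlation correction.  Below 10 points per sample the p-value is
    unreliable and a warning is emitted.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 10:
        warnings.warn("ks2d: fewer than 10 points; p-value unreliable", stacklevel=2)

    def sweep(origins):
        d = 0.0
        for o in origins:
            d = max(d, float(np.abs(
                _quadrant_fractions(a, o) - _quadrant_fractions(b, o)
            ).max()))
        return d

    d = 0.5 * (sweep(a) + sweep(b))
    n = n1 * n2 / (n1 + n2)

    def _corr(s):
        if len(s) < 2 or np.ptp(s[:, 0]) == 0 or np.ptp(s[:, 1]) == 0:
            return 0.0
        return float(np.corrcoef(s[:, 0], s[:, 1])[0, 1])

    r1, r2 = _corr(a), _corr(b)
    rr = math.sqrt(max(0.0, 1.0 - 0.5 * (r1 * r1 + r2 * r2)))
    lam = math.sqrt(n) * d / (1.0 + rr * (0.25 - 0.75 / math.sqrt(n)))
    p = float(sps.kstwobign.sf(lam))
    return d, min(1.0, p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank test (tie-corrected asymptotic
    normal approximation); returns (U of the first sample, p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def cohort_summary(results: list[dict], kde_resolution: int = 100) -> dict:
    """Per-group summary and pairwise between-group comparisons.

    ``results`` holds per-islet dicts with keys ``group``, ``beta_fraction``,
    ``log_total``, ``n_alpha``, ``n_delta``, ``ns_in_cycle`` (dict direction
    -> bool) and ``max_persistence`` (dict class -> float), as produced by
    the analysis pipeline.  The summary reports, per group, islet counts,
    the percentage of islets with at least one NS marker component fully
    inside a cycle in each direction, persistence percentiles and the KDE
    peak; and, for every group pair, KL divergences (both directions), the
    2D KS test on islet characteristics, and Mann-Whitney tests on maximum
    persistences.
    """
    groups: dict[str, list[dict]] = {}
    for r in results:
        groups.setdefault(r.get("group") or "all", []).append(r)
    names = sorted(groups)
    out: dict = {"groups": {}, "pairwise": {}}
    kdes: dict[str, KDEGrid | None] = {}

    samples = {
        g: np.array([[r["beta_fraction"], r["log_total"]] for r in rs])
        for g, rs in groups.items()
    }
    shared = default_ranges(list(samples.values())) if samples else None

    for g in names:
        rs = groups[g]
        n = len(rs)
        summary: dict = {"n_islets": n}
        for direction in ("ad_around_b", "b_around_ad"):
            flags = [bool(r["ns_in_cycle"].get(direction)) for r in rs]
            summary[f"pct_ns_in_cycle_{direction}"] = 100.0 * sum(flags) / n if n else 0.0
        for cls in ("beta", "alphadelta"):
            pers = np.array([r["max_persistence"][cls] for r in rs], dtype=float)
            summary[f"max_persistence_{cls}_median"] = float(np.median(pers)) if n else 0.0
            summary[f"max_persistence_{cls}_p95"] = (
                float(np.percentile(pers, 95)) if n else 0.0
            )
        summary["alpha_delta_counts"] = {
            "median_alpha": float(np.median([r["n_alpha"] for r in rs])) if n else 0.0,
            "median_delta": float(np.median([r["n_delta"] for r in rs])) if n else 0.0,
            "pct_more_alpha": 100.0
            * sum(r["n_alpha"] > r["n_delta"] for r in rs)
            / n
            if n
            else 0.0,
        }
        kde = None
        if n >= 3:
            try:
                kde = kde2d(samples[g], resolution=kde_resolution, ranges=shared)
            except ValueError:
                kde = None
        kdes[g] = kde
        if kde is not None:
            summary["kde_peak"] = list(kde.peak())
            summary["kde_bandwidth_rule"] = kde.bandwidth_rule
        out["groups"][g] = summary

    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            pair: dict = {}
            if kdes[ga] is not None and kdes[gb] is not None:
                pair["kl_ab"] = kl_divergence(kdes[ga], kdes[gb])
                pair["kl_ba"] = kl_divergence(kdes[gb], kdes[ga])
            if len(samples[ga]) >= 2 and len(samples[gb]) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stat, p = ks2d(samples[ga], samples[gb])
                pair["ks2d_statistic"] = stat
                pair["ks2d_p"] = p
            for cls in ("beta", "alphadelta"):
                pa = [r["max_persistence"][cls] for r in groups[ga]]
                pb = [r["max_persistence"][cls] for r in groups[gb]]
                if pa and pb:
                    u, p = mann_whitney(pa, pb)
                    pair[f"mw_max_persistence_{cls}_U"] = u
                    pair[f"mw_max_persistence_{cls}_p"] = p
            out["pairwise"][f"{ga}|{gb}"] = pair
    return out
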