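"""Distribution-comparison statistics.

``ks2d`` is the two-dimensional two-sample Kolmogorov-Smirnov test of
Fasano & Franceschini: around every data point of each sample, the
plane is split into four open quadrants and the statistic D is the
maximum absolute difference between the two samples' quadrant
fractions, averaged over the two per-sample origin passes.  Identical
samples give D = 0; samples confined to opposite quadrants around some
point give D = 1.  Points falling exactly on a dividing line (including
the origin itself) belong to no quadrant; fractions are taken over the
full sample size.  The p-value comes either from the asymptotic
Kolmogorov distribution with the Press-style correlation correction or
from a label permutation of the pooled points (the authoritative choice
for small samples).

``brown_forsythe`` tests equality of spread between two groups by a
one-way ANOVA on absolute deviations from the group medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["KSResult", "ks2d", "brown_forsythe"]


@dataclass
class KSResult:
    """Fasano-Franceschini result: D in [0, 1], p in (0, 1]."""

    D: float
    p: float
    n1: int
    n2: int
    method: str


def _max_quadrant_diff(origins: np.ndarray, a: np.ndarray,
                       b: np.ndarray) -> float:
    """Max over origins and quadrants of |fraction_a - fraction_b|."""
    best = 0.0
    ax, ay = a[:, 0], a[:, 1]
    bx, by = b[:, 0], b[:, 1]
    na, nb = len(a), len(b)
    for ox, oy in origins:
        agx, agy = ax > ox, ay > oy
        alx, aly = ax < ox, ay < oy
        bgx, bgy = bx > ox, by > oy
        blx, bly = bx < ox, by < oy
        for qa, qb in (((agx & agy), (bgx & bgy)),
                       ((alx & agy), (blx & bgy)),
                       ((alx & aly), (blx & bly)),
                       ((agx & aly), (bgx & bly))):
            d = abs(qa.sum() / na - qb.sum() / nb)
            if d > best:
                best = d
    return best


def _ff_statistic(a: np.ndarray, b: np.ndarray) -> float:
    d1 = _max_quadrant_diff(a, a, b)
    d2 = _max_quadrant_diff(b, a, b)
    return 0.5 * (d1 + d2)


def ks2d(sample_a: np.ndarray, sample_b: np.ndarray,
         method: str = "asymptotic", n_perms: int = 2000,
         rng: np.random.Generator | int | None = None) -> KSResult:
    """Two-sample 2D Kolmogorov-Smirnov (Fasano-Franceschini) test.

    Parameters
    ----------
    sample_a, sample_b : (n, 2) arrays of points.
    method : "asymptotic" or "permutation".
    n_perms : permutation count (permutation method only).
    rng : seed or Generator for the permutation method.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(sample_b, dtype=np.float64))
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("samples must be (n, 2) point arrays")
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each sample needs at least one point")
    if len(a) < 10 or len(b) < 10:
        import warnings
        warnings.warn("fewer than 10 points in a sample: the 2D KS test "
                      "has little power")
    D = _ff_statistic(a, b)
    n1, n2 = len(a), len(b)
    if method == "asymptotic":
        n_eff = n1 * n2 / (n1 + n2)
        r2 = []
        for s in (a, b):
            if len(s) > 1 and s[:, 0].std() > 0 and s[:, 1].std() > 0:
                r2.append(np.corrcoef(s[:, 0], s[:, 1])[0, 1] ** 2)
            else:
                r2.append(0.0)
        rr = np.sqrt(1.0 - 0.5 * (r2[0] + r2[1]))
        lam = np.sqrt(n_eff) * D / (1.0 + rr * (0.25 - 0.75 / np.sqrt(n_eff)))
        p = float(np.clip(sps.kstwobign.sf(lam), 0.0, 1.0))
    elif method == "permutation":
        gen = rng if isinstance(rng, np.random.Generator) \
            else np.random.default_rng(rng)
        pooled = np.vstack([a, b])
        count = 0
        for _ in range(n_perms):
            idx = gen.permutation(len(pooled))
            pa, pb = pooled[idx[:n1]], pooled[idx[n1:]]
            if _ff_statistic(pa, pb) >= D - 1e-12:
                count += 1
        p = (count + 1) / (n_perms + 1)
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return KSResult(D=float(D), p=float(p), n1=n1, n2=n2, method=method)


def brown_forsythe(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """p-value of the Brown-Forsythe test for equal spread.

    Each value is replaced by its absolute deviation from the group
    median, then a one-way ANOVA F-test compares the transformed
    groups.  Two groups with zero spread are identical by this
    criterion (p = 1).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    if za.std() == 0 and zb.std() == 0:
        return 1.0
    stat, p = sps.levene(a, b, center="median")
    return float(p)
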