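"""Trajectory post-processing: ellipse fits, rotation/drift correction,
axis projections and principal-axis relative positions.

Measured or simulated tissues rotate and drift while they elongate, so
raw cell tracks mix tissue-scale rigid motion with the intercalation
movements of interest.  The pipeline fits an ellipse to the tissue mask
of every frame, subtracts the ellipse center (drift) and rotates by the
ellipse orientation (rotation), leaving tracks expressed in the tissue
frame, where displacements along the long axis (v_l, normalized by the
long-axis length L) and the short axis (v_s, by S) can be compared
between experiment and simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel

from .shape import extract_contour

__all__ = ["EllipseFit", "fit_ellipse", "fit_ellipse_series",
           "correct_rotation_drift", "project_on_axes",
           "axis_relative_positions"]


@dataclass
class EllipseFit:
    """Ellipse center, semi-axes (long >= short) and orientation theta
    (angle of the long axis to the reference axis, counterclockwise;
    flagged unreliable for near-circular masks)."""

    center: np.ndarray
    long_axis: float
    short_axis: float
    theta: float
    reliable: bool = True


def fit_ellipse(mask: np.ndarray, min_axis_ratio: float = 1.05) -> EllipseFit:
    """Least-squares ellipse on the mask boundary points."""
    contour = extract_contour(mask)
    pts = contour.points
    if len(pts) > 400:  # the fit is dense enough on a subsample
        pts = pts[np.linspace(0, len(pts) - 1, 400).astype(int)]
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if b > a:
        a, b = b, a
        theta = theta + np.pi / 2
    theta = float(np.arctan2(np.sin(theta), np.cos(theta)))
    reliable = (a / max(b, 1e-12)) >= min_axis_ratio
    return EllipseFit(center=np.array([xc, yc]), long_axis=float(a),
                      short_axis=float(b), theta=theta, reliable=reliable)


def _nearest_representative(theta: float, reference: float) -> float:
    """The axis angle is defined modulo pi/2 swaps and pi flips; pick the
    representative theta + k*pi/2 closest to ``reference``."""
    k = np.round((reference - theta) / (np.pi / 2))
    return float(theta + k * np.pi / 2)


def fit_ellipse_series(masks: list[np.ndarray]) -> list[EllipseFit]:
    """Fit each frame and disambiguate theta across frames.

    Ellipse fitters often report theta off by pi/2 (axes swapped); each
    frame's angle is replaced by the representative closest to the
    previous frame, producing a continuous, unwrapped series.
    """
    fits = []
    prev = None
    for mask in masks:
        fit = fit_ellipse(mask)
        if prev is not None:
            fit.theta = _nearest_representative(fit.theta, prev)
        prev = fit.theta
        fits.append(fit)
    return fits


def _rotate(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return points @ R.T


def correct_rotation_drift(tracks: pd.DataFrame,
                           ellipses: list[EllipseFit],
                           frames: np.ndarray | None = None,
                           rotate_to_final: bool = False) -> pd.DataFrame:
    """Express tracks in the tissue frame.

    ``tracks`` has columns (cell_id, frame, x, y); ``ellipses`` one fit
    per frame (a missing fit -- None entry -- is linearly interpolated
    from its neighbors, with a warning).  Per frame the ellipse center
    is subtracted and positions are rotated by -theta.  With
    ``rotate_to_final`` the corrected tracks are re-rotated into the
    final frame's orientation for overlay plotting.
    """
    frames = np.asarray(sorted(tracks["frame"].unique())
                        if frames is None else frames)
    if len(frames) != len(ellipses):
        raise ValueError("one ellipse fit per frame required")
    thetas = np.array([e.theta if e is not None else np.nan for e in ellipses])
    centers = np.array([e.center if e is not None else (np.nan, np.nan)
                        for e in ellipses])
    if np.isnan(thetas).any():
        warnings.warn("missing ellipse fits: interpolating linearly")
        ok = ~np.isnan(thetas)
        idx = np.arange(len(thetas))
        thetas = np.interp(idx, idx[ok], thetas[ok])
        for col in range(2):
            centers[:, col] = np.interp(idx, idx[ok], centers[ok, col])
    lookup = {int(f): i for i, f in enumerate(frames)}
    out = tracks.copy()
    xy = out[["x", "y"]].to_numpy(dtype=float)
    for f, i in lookup.items():
        sel = out["frame"].to_numpy() == f
        p = xy[sel] - centers[i]
        xy[sel] = _rotate(p, -thetas[i])
    if rotate_to_final:
        xy = _rotate(xy, thetas[-1])
    out["x"] = xy[:, 0]
    out["y"] = xy[:, 1]
    return out


def project_on_axes(corrected: pd.DataFrame,
                    final_ellipse: EllipseFit) -> pd.DataFrame:
    """Per-cell net movement along the tissue axes.

    In the tissue frame x is the long axis and y the short axis.
    Returns one row per cell with v_l/L and v_s/S (net displacement
    over axis length, L = 2 * long semi-axis), the end positions, and a
    direction label relative to the long axis: "inward" (toward it),
    "outward" (away), or "crossing" (changed sides).
    """
    L = 2.0 * final_ellipse.long_axis
    S = 2.0 * final_ellipse.short_axis
    rows = []
    for cid, g in corrected.sort_values("frame").groupby("cell_id"):
        x0, y0 = g.iloc[0][["x", "y"]]
        x1, y1 = g.iloc[-1][["x", "y"]]
        if np.sign(y0) != np.sign(y1) and y0 != 0 and y1 != 0:
            label = "crossing"
        elif abs(y1) < abs(y0):
            label = "inward"
        else:
            label = "outward"
        rows.append({"cell_id": cid, "v_l": (x1 - x0) / L,
                     "v_s": (y1 - y0) / S, "x_end": x1, "y_end": y1,
                     "x_start": x0, "y_start": y0, "direction": label})
    return pd.DataFrame(rows)


def axis_relative_positions(points: np.ndarray,
                            region_mask: np.ndarray) -> np.ndarray:
    """Positions of points along the mask's principal axes, in [0, 1].

    The axes are the principal components of the mask pixel
    coordinates; projections are min-max scaled by the mask's own
    extent along each axis.  Points outside the extent are clipped with
    a warning.
    """
    mask = np.asarray(region_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty region mask")
    ys, xs = np.nonzero(mask)
    pix = np.column_stack([xs, ys]).astype(float)
    mean = pix.mean(axis=0)
    cov = np.cov((pix - mean).T)
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1]  # columns: long axis first
    proj_mask = (pix - mean) @ axes
    lo = proj_mask.min(axis=0)
    hi = proj_mask.max(axis=0)
    proj = (np.atleast_2d(np.asarray(points, float)) - mean) @ axes
    rel = (proj - lo) / (hi - lo)
    if (rel < 0).any() or (rel > 1).any():
        warnings.warn("points outside the mask extent were clipped")
        rel = np.clip(rel, 0.0, 1.0)
    return rel
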