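"""Synthetic data generators.

Everything the analysis modules consume can be generated here with
known ground truth: microscopy-like wide-field images (soft-edged blobs
plus sensor-like Gaussian noise) standing in for fixed-gastruloid
images, analytic shape families with known lobe structure for the
LOCO-EFA pipeline, and tracks advected by an incompressible stretch
flow (the idealized kinematics of convergent extension) for the
trajectory pipeline.  All generators are deterministic for a fixed
seed and also return their ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.filters import gaussian

from .shape import Contour, rasterize_contour

__all__ = ["SyntheticImageSpec", "make_widefield_image",
           "make_shape_family", "make_affine_flow_tracks"]


@dataclass
class SyntheticImageSpec:
    """Blueprint of a synthetic wide-field image."""

    shape: tuple[int, int] = (512, 512)
    centers: list[tuple[float, float]] = field(
        default_factory=lambda: [(160.0, 160.0), (352.0, 352.0)])
    radii: list[float] = field(default_factory=lambda: [60.0, 50.0])
    blur_sigma: float = 4.0
    noise_sd: float = 0.02
    bit_depth: int = 16
    overlap: bool = False

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.radii):
            raise ValueError("one radius per blob center")
        if not self.overlap:
            for i in range(len(self.centers)):
                for j in range(i + 1, len(self.centers)):
                    d = np.hypot(self.centers[i][0] - self.centers[j][0],
                                 self.centers[i][1] - self.centers[j][1])
                    if d < self.radii[i] + self.radii[j]:
                        raise ValueError("blobs overlap; set overlap=True "
                                         "to allow")


def make_widefield_image(spec: SyntheticImageSpec,
                         rng: np.random.Generator | int | None = None
                         ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Render soft-edged blobs plus Gaussian noise.

    Returns (image, ground-truth masks), the image as unsigned integers
    of the requested bit depth.
    """
    gen = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    canvas = np.zeros(spec.shape, dtype=np.float64)
    masks = []
    for (r, c), radius in zip(spec.centers, spec.radii):
        mask = np.zeros(spec.shape, dtype=bool)
        rr, cc = _draw_disk((r, c), radius, shape=spec.shape)
        mask[rr, cc] = True
        canvas[mask] = 1.0
        masks.append(mask)
    canvas = gaussian(canvas, sigma=spec.blur_sigma, preserve_range=True)
    canvas = canvas + gen.normal(0.0, spec.noise_sd, size=spec.shape)
    top = 2 ** spec.bit_depth - 1
    image = np.clip(canvas, 0.0, 1.0) * top
    dtype = np.uint16 if spec.bit_depth > 8 else np.uint8
    return image.astype(dtype), masks


def make_shape_family(kind: str, size: float = 60.0, *,
                      aspect: float = 2.0, lobes: int = 3,
                      amplitude: float = 0.2, separation: float = 1.2,
                      head: float = 0.7, n_points: int = 720,
                      canvas: int | None = None
                      ) -> tuple[Contour, np.ndarray]:
    """Analytic contour (and rasterized mask) with known lobe structure.

    kinds: "circle" (no lobes), "ellipse" (2-lobe dominant, semi-axes
    size*aspect and size), "flower" (r = size*(1 + amplitude*cos(n*theta)),
    n-lobe dominant), "snowman" (a disc of radius ``size`` overlapping a
    smaller "head" disc of radius ``head*size`` at center distance
    ``separation*size``: the unequal lobes mix 2- and 3-lobe content --
    equal discs would have no odd modes by symmetry).
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    if kind == "circle":
        x, y = size * np.cos(t), size * np.sin(t)
    elif kind == "ellipse":
        x, y = size * aspect * np.cos(t), size * np.sin(t)
    elif kind == "flower":
        if amplitude >= 1.0:
            raise ValueError("flower amplitude must be < 1 (self-intersects)")
        r = size * (1.0 + amplitude * np.cos(lobes * t))
        x, y = r * np.cos(t), r * np.sin(t)
    elif kind == "snowman":
        d = separation * size
        radii = (size, head * size)
        if not 0.0 < d < sum(radii):
            raise ValueError("snowman discs must overlap")
        if d / 2.0 >= min(radii):
            raise ValueError("snowman midpoint must lie inside both discs")
        # union outline, star-shaped around the midpoint of the centers
        cx = d / 2.0
        r = np.empty_like(t)
        for i, th in enumerate(t):
            best = 0.0
            for sgn, radius in ((-1.0, radii[0]), (1.0, radii[1])):
                # disc centered at (sgn*cx +- offset, 0)
                b = -2.0 * sgn * cx * np.cos(th)
                c = cx ** 2 - radius ** 2
                disc = b * b - 4.0 * c
                if disc >= 0:
                    root = (-b + np.sqrt(disc)) / 2.0
                    best = max(best, root)
            r[i] = best
        x, y = r * np.cos(t), r * np.sin(t)
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    contour = Contour(np.column_stack([x, y]))
    pad = 8
    if canvas is None:
        canvas = int(np.ceil(2 * np.abs(np.column_stack([x, y])).max())) + 2 * pad
    shifted = Contour(contour.points - contour.points.min(axis=0) + pad)
    mask = rasterize_contour(shifted, (canvas, canvas))
    return contour, mask


def make_affine_flow_tracks(stretch: float = 1.5, n_cells: int = 30,
                            n_frames: int = 10, *,
                            initial_stretch: float = 1.0,
                            blob_radius: float = 80.0,
                            rotation_per_frame: float = 0.0,
                            drift_per_frame: tuple[float, float] = (0.0, 0.0),
                            jitter: float = 0.0,
                            canvas: int = 400,
                            rng: np.random.Generator | int | None = None):
    """Cells advected by an incompressible stretch flow.

    Positions follow (x, y) -> (k_t x, y / k_t) with k_t interpolating
    geometrically from ``initial_stretch`` to ``stretch`` over the
    frames -- the textbook kinematics of convergent extension (a
    nonzero initial stretch keeps the long axis defined from the first
    frame) -- optionally composed with a
    rigid rotation/drift per frame and Gaussian jitter.  Returns
    (tracks DataFrame with cell_id/frame/x/y, list of per-frame masks
    of the advected elliptical blob).
    """
    import pandas as pd
    gen = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    # seed points inside a disc
    ang = gen.uniform(0, 2 * np.pi, n_cells)
    rad = blob_radius * np.sqrt(gen.uniform(0.05, 0.95, n_cells))
    p0 = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    center = np.array([canvas / 2.0, canvas / 2.0])
    rows = []
    masks = []
    theta_grid = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    for f in range(n_frames):
        frac = f / max(n_frames - 1, 1)
        k = initial_stretch * (stretch / initial_stretch) ** frac
        pts = p0 * np.array([k, 1.0 / k])
        phi = rotation_per_frame * f
        c, s = np.cos(phi), np.sin(phi)
        R = np.array([[c, -s], [s, c]])
        shift = center + np.asarray(drift_per_frame, float) * f
        pts = pts @ R.T + shift
        if jitter > 0:
            pts = pts + gen.normal(0.0, jitter, size=pts.shape)
        for cid, (x, y) in enumerate(pts):
            rows.append({"cell_id": cid, "frame": f, "x": x, "y": y})
        # blob mask: ellipse with the same stretch and rigid motion
        ex = blob_radius * k * np.cos(theta_grid)
        ey = (blob_radius / k) * np.sin(theta_grid)
        outline = np.column_stack([ex, ey]) @ R.T + shift
        masks.append(rasterize_contour(Contour(outline), (canvas, canvas)))
    return pd.DataFrame(rows), masks
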