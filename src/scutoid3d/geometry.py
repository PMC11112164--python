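"""Tissue-scale geometry: ellipsoid fits, curvatures, surface ratios.

The apical and basal surfaces of a spheroidal epithelium are modelled as
general (rotated) ellipsoids fitted by algebraic least squares to the
surface pixel clouds. Principal curvatures at any surface point follow in
closed form from the fitted quadric, via the shape operator of the
implicit surface. From per-cell curvatures the module derives:

* surface ratio anisotropy (SRA): with ``R`` the radius of curvature
  (1/k), the apical/basal ratios ``SR_h = R_a_h / R_b_h`` and
  ``SR_w = R_a_w / R_b_w`` are formed along the axes of greatest (h) and
  least (w) curvature, and ``sra = |SR_h - SR_w|``. Concentric spheres —
  isotropic curvature — give 0.
* tissue surface ratio: total apical area over total basal area,
  integrating each layer's depth heightfield as a triangulated surface.
* whole-embryo axis lengths and their aspect ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, RunConfig
from .topology import LayerMaps, label_centroids

__all__ = [
    "EllipsoidFit",
    "AnisotropyRecord",
    "fit_ellipsoid",
    "principal_curvatures",
    "surface_ratio_anisotropy",
    "tissue_surface_ratio",
    "heightfield_area",
    "embryo_axes",
]


@dataclass(frozen=True)
class EllipsoidFit:
    """A fitted general ellipsoid.

    ``axes[:, i]`` is the unit direction of semi-axis ``semiaxes[i]``;
    semi-axes are sorted descending. ``matrix`` is the quadric matrix A of
    the centred form (x-c)ᵀ A (x-c) = 1. ``residual`` is the RMS radial
    misfit in µm.
    """

    centre: np.ndarray
    semiaxes: np.ndarray
    axes: np.ndarray
    matrix: np.ndarray
    residual: float


def fit_ellipsoid(points: np.ndarray) -> EllipsoidFit:
    """Algebraic least-squares fit of a general ellipsoid to 3D points.

    Solves the quadric ``xᵀMx + bᵀx = 1`` in the nine coefficients by
    linear least squares, then recovers centre, semi-axes and orientation.
    Raises if fewer than 9 points are supplied or the best-fitting quadric
    is not an ellipsoid (non-positive-definite).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 9:
        raise ValueError(f"need at least 9 points, got {len(pts)}")
    # centre/scale for conditioning
    shift = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale == 0:
        raise ValueError("degenerate point cloud")
    q = (pts - shift) / scale
    z, y, x = q[:, 0], q[:, 1], q[:, 2]
    design = np.column_stack(
        [z * z, y * y, x * x, z * y, z * x, y * x, z, y, x]
    )
    coef, *_ = np.linalg.lstsq(design, np.ones(len(q)), rcond=None)
    A, B, C, D, E, F, G, H, I = coef
    M = np.array([[A, D / 2, E / 2], [D / 2, B, F / 2], [E / 2, F / 2, C]])
    b = np.array([G, H, I])
    try:
        centre_q = np.linalg.solve(2 * M, -b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate quadric: cannot locate centre") from exc
    # constant of the centred form yᵀMy = k with y = x − c
    k = 1.0 - (centre_q @ M @ centre_q + b @ centre_q)
    # centred quadric: yᵀ M y = k  →  A = M / k
    if k <= 0:
        raise ValueError("fitted quadric is not an ellipsoid")
    A_q = M / k
    evals, evecs = np.linalg.eigh(A_q)
    if np.any(evals <= 0):
        raise ValueError("fitted quadric is not an ellipsoid")
    semi_q = 1.0 / np.sqrt(evals)  # ascending evals → descending axes
    order = np.argsort(semi_q)[::-1]
    semi = semi_q[order] * scale
    axes = evecs[:, order]
    centre = centre_q * scale + shift
    A_world = A_q / scale**2  # same eigvecs, scaled lengths

    # RMS radial residual
    rel = pts - centre
    r = np.linalg.norm(rel, axis=1)
    nonzero = r > 0
    u = rel[nonzero] / r[nonzero, None]
    r_surf = 1.0 / np.sqrt(np.einsum("ij,jk,ik->i", u, A_world, u))
    residual = float(np.sqrt(np.mean((r[nonzero] - r_surf) ** 2)))
    return EllipsoidFit(
        centre=centre, semiaxes=semi, axes=axes, matrix=A_world, residual=residual
    )


def project_to_surface(fit: EllipsoidFit, point: np.ndarray) -> np.ndarray:
    """Radially project a point (from the fit centre) onto the ellipsoid."""
    rel = np.asarray(point, dtype=float) - fit.centre
    q = np.sqrt(rel @ fit.matrix @ rel)
    if q == 0:
        raise ValueError("point coincides with the ellipsoid centre")
    return fit.centre + rel / q


def principal_curvatures(fit: EllipsoidFit, point: np.ndarray) -> tuple[float, float]:
    """Principal curvatures (k_h, k_w), k_h ≥ k_w > 0, at a surface point.

    The point is first radially projected onto the fitted ellipsoid. The
    curvatures are the nonzero eigenvalues of the shape operator
    ``P H P / |∇F|`` of the implicit surface ``F(x) = xᵀAx − 1``, with
    ``P`` the tangent-plane projector. For a sphere of radius R both equal
    1/R; for a spheroid (a, a, c) the pole on the c axis gives c/a² twice,
    and the equator gives a/c² and 1/a.
    """
    p = project_to_surface(fit, point)
    rel = p - fit.centre
    grad = 2.0 * fit.matrix @ rel
    gnorm = np.linalg.norm(grad)
    n = grad / gnorm
    P = np.eye(3) - np.outer(n, n)
    S = P @ (2.0 * fit.matrix) @ P / gnorm
    evals = np.linalg.eigvalsh(S)
    # two tangential eigenvalues; the normal direction contributes ~0
    k = sorted(evals, key=abs, reverse=True)[:2]
    k_h, k_w = max(k), min(k)
    return float(k_h), float(k_w)


@dataclass(frozen=True)
class AnisotropyRecord:
    """Mean apical/basal radii of curvature and the derived anisotropy.

    ``R_*_h`` are mean radii along the axis of greatest curvature (h),
    ``R_*_w`` along the axis of least curvature (w); ``SR_h`` and ``SR_w``
    the apical/basal ratios; ``sra = |SR_h − SR_w|`` (0 = isotropic).
    """

    R_a_h: float
    R_a_w: float
    R_b_h: float
    R_b_w: float
    SR_h: float
    SR_w: float
    sra: float
    apical_residual: float
    basal_residual: float


def _layer_points(
    labels2d: np.ndarray, depth: np.ndarray, spacing, max_points: int = 20000
) -> np.ndarray:
    dz, dy, dx = spacing
    pix = np.argwhere(labels2d > 0)
    if len(pix) > max_points:
        stride = int(np.ceil(len(pix) / max_points))
        pix = pix[::stride]
    z = depth[pix[:, 0], pix[:, 1]] * dz
    return np.column_stack([z, pix[:, 0] * dy, pix[:, 1] * dx])


def surface_ratio_anisotropy(
    volume: LabelVolume,
    layers: LayerMaps,
    selected: set[int],
    config: RunConfig | None = None,
) -> AnisotropyRecord:
    """Curvature anisotropy of the imaged region from per-cell curvatures.

    Ellipsoids are fitted to the apical and basal surface pixel clouds; at
    each selected cell centroid (projected to each surface) the principal
    curvatures give per-cell radii. Radii are averaged per surface and per
    axis class before forming the apical/basal ratios (switchable to
    per-cell ratios first via ``config.radii_average_order``).
    """
    if len(selected) < 9:
        raise ValueError("need at least 9 selected cells")
    config = config or RunConfig()
    apical_fit = fit_ellipsoid(
        _layer_points(layers.apical_labels, layers.apical_depth, volume.spacing)
    )
    basal_fit = fit_ellipsoid(
        _layer_points(layers.basal_labels, layers.basal_depth, volume.spacing)
    )
    centroids = label_centroids(volume)
    Ra_h, Ra_w, Rb_h, Rb_w = [], [], [], []
    for l in sorted(selected):
        if l not in centroids:
            continue
        c = centroids[l]
        ka_h, ka_w = principal_curvatures(apical_fit, c)
        kb_h, kb_w = principal_curvatures(basal_fit, c)
        Ra_h.append(1.0 / ka_h)
        Ra_w.append(1.0 / ka_w)
        Rb_h.append(1.0 / kb_h)
        Rb_w.append(1.0 / kb_w)
    if config.radii_average_order == "radii-then-ratio":
        R_a_h, R_a_w = np.mean(Ra_h), np.mean(Ra_w)
        R_b_h, R_b_w = np.mean(Rb_h), np.mean(Rb_w)
        SR_h = R_a_h / R_b_h
        SR_w = R_a_w / R_b_w
    else:
        R_a_h, R_a_w = np.mean(Ra_h), np.mean(Ra_w)
        R_b_h, R_b_w = np.mean(Rb_h), np.mean(Rb_w)
        SR_h = float(np.mean(np.asarray(Ra_h) / np.asarray(Rb_h)))
        SR_w = float(np.mean(np.asarray(Ra_w) / np.asarray(Rb_w)))
    return AnisotropyRecord(
        R_a_h=float(R_a_h),
        R_a_w=float(R_a_w),
        R_b_h=float(R_b_h),
        R_b_w=float(R_b_w),
        SR_h=float(SR_h),
        SR_w=float(SR_w),
        sra=float(abs(SR_h - SR_w)),
        apical_residual=apical_fit.residual,
        basal_residual=basal_fit.residual,
    )


def heightfield_area(
    depth: np.ndarray, spacing, keep: np.ndarray | None = None
) -> float:
    """Area (µm²) of a depth heightfield, triangulating each defined quad.

    Pixels with depth < 0 are undefined; a quad contributes only when all
    four of its corners are defined (and in ``keep``, when given). Each
    quad is split into two triangles whose vertices sit at the pixel
    centres with z = depth·dz.
    """
    dz, dy, dx = spacing
    defined = depth >= 0
    if keep is not None:
        defined = defined & keep
    z = depth * dz
    ny, nx = depth.shape
    yy, xx = np.indices((ny, nx))
    pts = np.stack([z, yy * dy, xx * dx], axis=-1)
    a = pts[:-1, :-1]
    b = pts[:-1, 1:]
    c = pts[1:, :-1]
    d = pts[1:, 1:]
    ok = defined[:-1, :-1] & defined[:-1, 1:] & defined[1:, :-1] & defined[1:, 1:]
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
    t2 = 0.5 * np.linalg.norm(np.cross(b - d, c - d), axis=-1)
    return float(np.sum((t1 + t2)[ok]))


def tissue_surface_ratio(
    layers: LayerMaps, spacing, labels: set[int] | None = None
) -> float:
    """Tissue apical surface area divided by tissue basal surface area.

    When ``labels`` is given, both integrals are restricted to the
    footprints of those cells, so the two surfaces cover the same tissue
    (the same solid angle of a curved shell) rather than the same image
    region; the ratio then exceeds 1 for an outward-curved monolayer with
    the apical side out. Exceeds 1 more for thicker tissue.
    """
    keep_a = keep_b = None
    if labels is not None:
        keep_a = np.isin(layers.apical_labels, list(labels))
        keep_b = np.isin(layers.basal_labels, list(labels))
    apical = heightfield_area(layers.apical_depth, spacing, keep_a)
    basal = heightfield_area(layers.basal_depth, spacing, keep_b)
    if basal <= 0:
        raise ValueError("empty basal surface")
    return apical / basal


def embryo_axes(volume: LabelVolume) -> tuple[np.ndarray, float, float]:
    """Whole-embryo axis lengths from an ellipsoid fit of the outer surface.

    Returns ``(lengths, aspect_ratio, major_axes_ratio)`` where lengths are
    twice the fitted semi-axes (descending, µm), aspect ratio is
    longest/shortest and the major-axes ratio longest/second-longest
    (≈1 for an oblate spheroid).
    """
    mask = volume.voxels > 0
    if not np.any(mask):
        raise ValueError("empty volume")
    surface = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(surface) * np.asarray(volume.spacing)
    fit = fit_ellipsoid(pts)
    lengths = 2.0 * fit.semiaxes
    return lengths, float(lengths[0] / lengths[2]), float(lengths[0] / lengths[1])
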