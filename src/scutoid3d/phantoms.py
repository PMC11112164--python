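"""Synthetic epithelium phantoms with known ground truth.

Every downstream stage of the pipeline — layer extraction, scutoid calling,
morphometrics, curvature fits, Voronoi null models and event timing — is
exercised on volumes produced here, so nothing needs to be downloaded to
test the package end to end.

The main phantom emulates a monolayered epithelium wrapped around a
spheroidal shell (a blastula-like geometry): cells are Voronoi regions of
seeds scattered quasi-uniformly over the mid-surface ellipsoid, so each
cell spans the full apico-basal thickness of the shell. Simple deterministic
phantoms (prism lattices, a four-cell scutoid motif) provide exact oracles
for the topology code, and a seed-splitting simulator emulates rounds of
synchronous cell division.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import LabelVolume

__all__ = [
    "PhantomSpec",
    "TimelapseSpec",
    "default_phantom_spec",
    "make_shell_mask",
    "make_voronoi_epithelium",
    "make_prism_lattice",
    "make_scutoid_quartet",
    "inject_opening",
    "simulate_division_series",
    "synchronous_wave_spec",
    "sample_onset_times",
]

#: golden angle in radians, used for the quasi-uniform spiral lattice
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling parameters of a spheroidal-shell phantom.

    Semi-axes are in µm and ordered ``(z, y, x)`` like the voxel grid;
    ``spacing`` is the voxel size ``(dz, dy, dx)`` in µm and ``shape`` the
    grid dimensions ``(nz, ny, nx)``. ``jitter`` is the standard deviation
    (µm) of the Gaussian displacement added to each lattice seed.
    ``opening_caps`` lists ``(unit direction, angular radius in rad)`` pairs
    of spherical caps to clear of cells, emulating unsealed regions.

    ``cap_angle`` restricts the shell (and the seeds) to the imaged patch
    around the objective-facing pole (the low-z side). The default π keeps
    the full closed shell; any smaller value keeps only the near half
    (z below the equator) cropped laterally by a vertical cylinder of
    radius ``inner_lateral · sin(cap_angle)``. Both cuts run parallel or
    perpendicular to the scan axis, so the top-down/bottom-up scans of the
    patch always yield the outer (apical) and inner (basal) surfaces of
    the monolayer, never a cut face — mimicking a confocal stack cropped
    to the embryo surface closest to the objective.
    """

    outer_semiaxes: tuple[float, float, float]
    inner_semiaxes: tuple[float, float, float]
    n_cells: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shape: tuple[int, int, int] | None = None
    jitter: float = 0.0
    opening_caps: tuple[tuple[tuple[float, float, float], float], ...] = ()
    cap_angle: float = float(np.pi)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        outer = tuple(float(v) for v in self.outer_semiaxes)
        inner = tuple(float(v) for v in self.inner_semiaxes)
        if any(i >= o for i, o in zip(inner, outer)):
            raise ValueError("inner semi-axes must be strictly inside outer semi-axes")
        if any(v <= 0 for v in outer) or any(v < 0 for v in inner):
            raise ValueError("semi-axes must be positive (inner may be 0)")
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing components must be > 0")
        if not 0.0 < self.cap_angle <= np.pi:
            raise ValueError("cap_angle must lie in (0, pi]")
        shape = self.shape
        if shape is None:
            if self.cap_angle < np.pi and min(inner[1:]) > 0:
                # span the cylindrical view crop exactly in y/x so that
                # cells cut by the crop touch the image boundary (and are
                # border-flagged downstream); full extent in z
                sin_cap = float(np.sin(min(self.cap_angle, np.pi / 2)))
                nz = int(np.ceil(2 * outer[0] / spacing[0])) + 2
                ny = int(np.ceil(2 * inner[1] * sin_cap / spacing[1]))
                nx = int(np.ceil(2 * inner[2] * sin_cap / spacing[2]))
                shape = (nz, ny, nx)
            else:
                # fit the outer ellipsoid with a one-voxel margin per side
                shape = tuple(
                    int(np.ceil(2 * o / s)) + 2 for o, s in zip(outer, spacing)
                )
        object.__setattr__(self, "outer_semiaxes", outer)
        object.__setattr__(self, "inner_semiaxes", inner)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", tuple(int(n) for n in shape))

    @property
    def mid_semiaxes(self) -> tuple[float, float, float]:
        return tuple(
            (o + i) / 2 for o, i in zip(self.outer_semiaxes, self.inner_semiaxes)
        )


def default_phantom_spec(
    n_cells: int = 150,
    compression: float = 1.0,
    rng_seed: int = 0,
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> PhantomSpec:
    """A blastula-scale shell phantom.

    Defaults emulate the well-imaged patch of an early spheroidal blastula:
    outer radius 80 µm, epithelium 25 µm thick, ~150 cells on the imaged
    patch (a few hundred per hemisphere), 1 µm of seed jitter, and a
    1.1 rad view crop facing the objective (so the apical/basal z-scans
    see only the near monolayer).

    ``compression < 1`` squashes one lateral semi-axis, turning the embryo
    into an oblate spheroid whose short axis lies perpendicular to the
    viewing axis. This reproduces the two signatures of a mechanically
    confined embryo as seen in its imaged region: anisotropic curvature
    (unequal principal radii at the pole patch) and a higher areal cell
    density at matched cell counts. Squashing along the viewing axis
    instead would merely flatten the imaged patch, which lowers both.
    """
    outer = (80.0, 80.0 * compression, 80.0)
    inner = (55.0, 55.0 * compression, 55.0)
    return PhantomSpec(
        outer_semiaxes=outer,
        inner_semiaxes=inner,
        n_cells=n_cells,
        spacing=spacing,
        jitter=1.0,
        cap_angle=1.1,
        rng_seed=rng_seed,
    )


def _grid_coords(shape, spacing):
    """Physical (z, y, x) coordinates of voxel centres, relative to grid centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def make_shell_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the ellipsoidal shell between inner and outer surfaces.

    A voxel belongs to the shell iff its physical centre lies inside the
    outer ellipsoid and outside (or on) the inner ellipsoid.
    """
    thickness = np.subtract(spec.outer_semiaxes, spec.inner_semiaxes)
    if np.any(thickness < np.asarray(spec.spacing)):
        raise ValueError(
            f"degenerate shell: thickness {tuple(thickness)} µm is below one voxel "
            f"{spec.spacing} µm along some axis"
        )
    zz, yy, xx = _grid_coords(spec.shape, spec.spacing)
    oz, oy, ox = spec.outer_semiaxes
    shell = (zz / oz) ** 2 + (yy / oy) ** 2 + (xx / ox) ** 2 <= 1.0
    iz, iy, ix = spec.inner_semiaxes
    if min(iz, iy, ix) > 0:
        inner = (zz / iz) ** 2 + (yy / iy) ** 2 + (xx / ix) ** 2 < 1.0
        shell &= ~inner
    if spec.cap_angle < np.pi:
        shell &= zz <= 0  # near half only (z index 0 faces the objective)
        if min(iy, ix) > 0:
            s = np.sin(min(spec.cap_angle, np.pi / 2))
            shell &= (yy / (iy * s)) ** 2 + (xx / (ix * s)) ** 2 <= 1.0
    return shell


def _spiral_seeds(spec: PhantomSpec) -> np.ndarray:
    """Quasi-uniform seed positions on the mid-surface ellipsoid (µm, z/y/x).

    A golden-angle spiral lattice on the unit sphere (restricted to the
    spec's polar cap) is scaled to the mid-surface semi-axes, then jittered
    with Gaussian noise of s.d. ``spec.jitter`` and re-projected onto the
    mid-surface, so the perturbation is tangential: seeds model cell
    centres, which lie in the mid-plane of a monolayer. (An off-surface
    radial offset would tilt the Voronoi walls through the whole shell
    thickness, a much stronger and unphysical perturbation.) Deterministic
    for a fixed ``rng_seed``.
    """
    n = spec.n_cells
    i = np.arange(n)
    if spec.cap_angle < np.pi:
        # keep seeds inside the cylindrical view crop: mid-surface lateral
        # extent must stay within inner_lateral * sin(cap_angle)
        i_lat = float(np.mean(spec.inner_semiaxes[1:]))
        m_lat = float(np.mean(spec.mid_semiaxes[1:]))
        s = np.sin(min(spec.cap_angle, np.pi / 2)) * i_lat / m_lat
        theta_max = np.arcsin(min(1.0, 0.98 * s))
    else:
        theta_max = np.pi
    # polar angle from the objective-facing pole: cos uniform over the cap
    c = 1.0 - (1.0 - np.cos(theta_max)) * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - c * c, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    # pole points toward negative z (z index 0 is closest to the objective)
    unit = np.stack([-c, r * np.sin(phi), r * np.cos(phi)], axis=1)
    seeds = unit * np.asarray(spec.mid_semiaxes)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.rng_seed)
        seeds = seeds + rng.normal(0.0, spec.jitter, size=seeds.shape)
        seeds = np.array(
            [_project_to_ellipsoid(s, spec.mid_semiaxes) for s in seeds]
        )
    return seeds


def make_voronoi_epithelium(
    spec: PhantomSpec,
) -> tuple[LabelVolume, pd.DataFrame]:
    """Generate a shell epithelium by nearest-seed tiling of the shell mask.

    Returns the label volume (labels ``1..n_cells``) and a seed table with
    columns ``cell_id, z_um, y_um, x_um`` (coordinates relative to the grid
    centre).
    """
    from .voronoi_null import nearest_seed_labels  # local import: avoid cycle

    mask = make_shell_mask(spec)
    n_in_mask = int(mask.sum())
    if spec.n_cells > n_in_mask:
        raise ValueError(
            f"n_cells={spec.n_cells} exceeds the {n_in_mask} voxels of the shell mask"
        )
    seeds = _spiral_seeds(spec)
    vox = nearest_seed_labels(seeds, mask, spec.spacing, origin="center")
    volume = LabelVolume(voxels=vox, spacing=spec.spacing)
    for direction, radius in spec.opening_caps:
        volume = inject_opening(volume, direction, radius)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, spec.n_cells + 1),
            "z_um": seeds[:, 0],
            "y_um": seeds[:, 1],
            "x_um": seeds[:, 2],
        }
    )
    return volume, table


def make_prism_lattice(
    n_x: int,
    n_y: int,
    cell_xy: float = 10.0,
    height: float = 20.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """Rectangular lattice of ``n_x * n_y`` prism cells; zero scutoids.

    Every cell is a constant rectangular column through all z slices, so
    apical and basal neighbour sets coincide by construction. Serves as the
    zero-scutoid ground truth.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("lattice counts must be >= 1")
    dz, dy, dx = spacing
    px = max(1, round(cell_xy / dx))
    py = max(1, round(cell_xy / dy))
    nz = max(1, round(height / dz))
    vox = np.zeros((nz, n_y * py, n_x * px), dtype=np.int64)
    label = 1
    for iy in range(n_y):
        for ix in range(n_x):
            vox[:, iy * py : (iy + 1) * py, ix * px : (ix + 1) * px] = label
            label += 1
    return LabelVolume(voxels=vox, spacing=spacing)


def make_scutoid_quartet(
    transition_frac: float,
    cell_xy: float = 10.0,
    height: float = 20.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """Four-cell motif undergoing an apico-basal neighbour exchange.

    Cells A=1, B=2, C=3, D=4 occupy a 2x2 physical block. On apical slices
    (z below the transition slice) the mid-wall layout lets A and B share an
    edge while C and D are separated; on basal slices the pairing flips to
    C–D. All four cells therefore have different apical and basal neighbour
    sets — the minimal scutoid motif. The transition slice index is
    ``round(transition_frac * n_z)``.

    The slice layouts use a one-cell-wide middle band (never a corner
    contact), so neighbourhood is unambiguous under any connectivity. A
    two-pixel background margin surrounds the motif so that none of the
    four cells is border-flagged downstream.
    """
    if not 0.0 < transition_frac < 1.0:
        raise ValueError("transition_frac must lie strictly in (0, 1)")
    dz, dy, dx = spacing
    px = max(2, round(cell_xy / dx))
    py = max(2, round(cell_xy / dy))
    nz = round(height / dz)
    if nz < 3:
        raise ValueError("need at least 3 z slices for a transition")
    ny, nx = 2 * py, 2 * px
    ymid, xmid = py, px
    # band half-widths for the middle column/row (>=1 px each side)
    bx = max(1, px // 2)
    by = max(1, py // 2)

    apical = np.zeros((ny, nx), dtype=np.int64)
    # A–B share the horizontal edge of the middle column; C left, D right
    apical[:, : xmid - bx] = 3
    apical[:, xmid + bx :] = 4
    apical[:ymid, xmid - bx : xmid + bx] = 1
    apical[ymid:, xmid - bx : xmid + bx] = 2

    basal = np.zeros((ny, nx), dtype=np.int64)
    # C–D share the vertical edge of the middle row; A top, B bottom
    basal[: ymid - by, :] = 1
    basal[ymid + by :, :] = 2
    basal[ymid - by : ymid + by, :xmid] = 3
    basal[ymid - by : ymid + by, xmid:] = 4

    t = int(round(transition_frac * nz))
    t = min(max(t, 1), nz - 1)  # both conformations must exist
    vox = np.empty((nz, ny, nx), dtype=np.int64)
    vox[:t] = apical
    vox[t:] = basal
    vox = np.pad(vox, ((0, 0), (2, 2), (2, 2)))
    return LabelVolume(voxels=vox, spacing=spacing)


def inject_opening(
    volume: LabelVolume,
    direction: tuple[float, float, float],
    angular_radius: float,
) -> LabelVolume:
    """Clear the cells of a spherical cap, emulating an unsealed opening.

    Labels whose centroid direction from the grid centre lies within
    ``angular_radius`` (rad) of ``direction`` (a (z, y, x) vector) are set
    to background.
    """
    if angular_radius <= 0:
        warnings.warn("angular_radius <= 0: no cells removed", stacklevel=2)
        return volume
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / norm
    vox = volume.voxels
    labels = volume.labels()
    # physical centroids relative to the grid centre
    centre = (np.asarray(vox.shape) - 1) / 2.0 * np.asarray(volume.spacing)
    idx = np.argwhere(vox > 0)
    lab = vox[vox > 0]
    coords = idx * np.asarray(volume.spacing) - centre
    sums = np.zeros((labels.max() + 1, 3))
    counts = np.bincount(lab, minlength=labels.max() + 1).astype(float)
    for axis in range(3):
        sums[:, axis] = np.bincount(lab, weights=coords[:, axis], minlength=labels.max() + 1)
    remove = []
    for l in labels:
        c = sums[l] / counts[l]
        r = np.linalg.norm(c)
        if r == 0:
            continue
        angle = np.arccos(np.clip(np.dot(c / r, d), -1.0, 1.0))
        if angle <= angular_radius:
            remove.append(l)
    out = vox.copy()
    out[np.isin(out, remove)] = 0
    return volume.with_voxels(out)


@dataclass(frozen=True)
class TimelapseSpec:
    """A division time-lapse: base geometry plus a division schedule.

    ``division_frames`` maps a frame index to the set of cell ids dividing
    at that frame (or the string ``"all"`` for a synchronous wave). Each
    dividing seed is replaced by two daughter seeds offset ±displacement/2
    along a random tangent of the mid-surface.
    """

    base: PhantomSpec
    n_frames: int
    division_frames: dict = field(default_factory=dict)
    displacement: float = 6.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        for frame in self.division_frames:
            if not 0 <= frame < self.n_frames:
                raise ValueError(
                    f"division frame {frame} outside [0, {self.n_frames})"
                )


def synchronous_wave_spec(
    base: PhantomSpec,
    n_waves: int = 3,
    frames_per_stage: int = 1,
    displacement: float = 6.0,
) -> TimelapseSpec:
    """Schedule ``n_waves`` synchronous divisions, one per stage boundary.

    Stage s occupies ``frames_per_stage`` frames; every cell divides at the
    first frame of each new stage (frames ``frames_per_stage * (s+1)``).
    """
    division_frames = {
        frames_per_stage * (w + 1): "all" for w in range(n_waves)
    }
    n_frames = frames_per_stage * (n_waves + 1)
    return TimelapseSpec(
        base=base,
        n_frames=n_frames,
        division_frames=division_frames,
        displacement=displacement,
    )


def _surface_normal(point: np.ndarray, semiaxes) -> np.ndarray:
    n = point / np.asarray(semiaxes) ** 2
    return n / np.linalg.norm(n)


def _project_to_ellipsoid(point: np.ndarray, semiaxes) -> np.ndarray:
    """Radially rescale a point onto the ellipsoid surface."""
    q = np.sqrt(np.sum((point / np.asarray(semiaxes)) ** 2))
    if q == 0:
        raise ValueError("cannot project the centre point")
    return point / q


def simulate_division_series(
    spec: TimelapseSpec,
) -> tuple[list[LabelVolume], pd.DataFrame]:
    """Simulate rounds of cell division on the shell phantom.

    At each scheduled division frame, each dividing seed is replaced by two
    daughter seeds offset ``±displacement/2`` along a random tangent of the
    mid-surface, then projected back onto it; the Voronoi tiling of the
    (static) shell mask is regenerated. Divisions perpendicular to the
    apico-basal axis emulate the planar, oriented divisions that thin and
    laterally expand a proliferating monolayer.

    Returns one labelled volume per frame and an event table with columns
    ``cell_id, parent_id, division_frame, interphase_start, interphase_end``
    (``division_frame`` is the frame at which the cell was born; -1 for the
    founding cells).
    """
    from .voronoi_null import nearest_seed_labels

    base = spec.base
    rng = np.random.default_rng(base.rng_seed)
    mask = make_shell_mask(base)
    mid = base.mid_semiaxes

    # rough local cell diameter on the mid-surface, for the sanity warning
    mean_r = float(np.mean(mid))
    cap_area = 2.0 * np.pi * mean_r**2 * (1.0 - np.cos(base.cap_angle))
    approx_diam = 2.0 * np.sqrt(cap_area / (np.pi * base.n_cells))
    if spec.displacement > approx_diam:
        warnings.warn(
            f"displacement {spec.displacement} µm exceeds the approximate local "
            f"cell diameter {approx_diam:.1f} µm",
            stacklevel=2,
        )

    seeds: dict[int, np.ndarray] = {
        i + 1: s for i, s in enumerate(_spiral_seeds(base))
    }
    born: dict[int, int] = {cid: -1 for cid in seeds}
    parent: dict[int, int] = {cid: 0 for cid in seeds}
    divided_at: dict[int, int] = {}
    next_id = base.n_cells + 1

    volumes: list[LabelVolume] = []
    for frame in range(spec.n_frames):
        dividing = spec.division_frames.get(frame, set())
        if dividing == "all":
            dividing = set(seeds)
        for cid in sorted(dividing):
            if cid not in seeds:
                raise ValueError(f"cell {cid} scheduled to divide but not alive")
            pos = seeds.pop(cid)
            divided_at[cid] = frame
            normal = _surface_normal(pos, mid)
            tangent = rng.normal(size=3)
            tangent -= tangent.dot(normal) * normal
            tangent /= np.linalg.norm(tangent)
            for sign in (+1.0, -1.0):
                child = _project_to_ellipsoid(
                    pos + sign * tangent * spec.displacement / 2.0, mid
                )
                seeds[next_id] = child
                born[next_id] = frame
                parent[next_id] = cid
                next_id += 1
        ids = np.array(sorted(seeds))
        pts = np.array([seeds[i] for i in ids])
        vox = nearest_seed_labels(pts, mask, base.spacing, origin="center", labels=ids)
        volumes.append(
            LabelVolume(voxels=vox, spacing=base.spacing, frame_index=frame)
        )

    rows = []
    for cid in sorted(born):
        start = max(born[cid], 0)
        end = divided_at.get(cid, spec.n_frames - 1)
        rows.append(
            {
                "cell_id": cid,
                "parent_id": parent[cid],
                "division_frame": born[cid],
                "interphase_start": start,
                "interphase_end": end,
            }
        )
    return volumes, pd.DataFrame(rows)


def sample_onset_times(
    n: int,
    p_after: float,
    threshold: float = 0.15,
    rng_seed: int = 0,
) -> np.ndarray:
    """Draw normalized scutoid onset times from a two-component mixture.

    With probability ``p_after`` an onset is uniform on ``[0, threshold)``
    (the after-mitosis window); otherwise uniform on ``[threshold, 1)``.
    Used for recovery tests of the onset classifier.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p_after <= 1.0:
        raise ValueError("p_after must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    after = rng.random(n) < p_after
    early = rng.uniform(0.0, threshold, size=n)
    late = rng.uniform(threshold, 1.0, size=n)
    return np.where(after, early, late)
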