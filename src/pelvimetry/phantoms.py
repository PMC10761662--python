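"""Synthetic pelvic label-map phantoms with analytically known measurements.

The generator builds a coronal and a sagittal multi-label volume carrying the
same structures a segmentation model would produce — prostate, membranous
urethra, corpus spongiosum, bladder (sagittal), and the paired obturator
internus / levator ani muscles (coronal) — from geometric primitives whose
true measurement values are known by construction:

* the urethra is a tube swept along a piecewise-linear centerline confined to
  the mid through-plane slice, so the true MUL is the centerline arc length;
* the bladder-prostate interface is flat, with an optional semicircular
  prostatic bump of known height protruding into the bladder (the true IPPL);
* each muscle is a rotated slab of known thickness.

Axis convention: axis 0 runs superior to inferior (image rows), axis 1 is the
in-plane left-right (coronal) or anterior-posterior (sagittal) direction, and
axis 2 is the through-plane stack.  The default spacing (0.63, 0.63, 3.0) mm
and 160x160x24 grid mirror a typical T2-weighted pelvic acquisition
(sub-millimetre in-plane, 3 mm slices) while keeping generation sub-second.

Phantoms are geometric scenes, not anatomy: organs are ellipsoids and slabs.
That is exactly what makes them usable as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .label_volumes import BinaryMask3D, LabelSchema, LabelVolume
from .seg_metrics import surface_voxels

CORONAL_LABELS = {"prostate": 1, "urethra": 2, "corpus_spongiosum": 3,
                  "oim_left": 4, "oim_right": 5, "lam_left": 6,
                  "lam_right": 7}
SAGITTAL_LABELS = {"prostate": 1, "urethra": 2, "corpus_spongiosum": 3,
                   "bladder": 4}

#: Measurement names carried in every phantom's truth mapping.
TRUTH_KEYS = ("coronal_mul", "sagittal_mul", "ippl", "lam_thickness",
              "oim_thickness", "lam_thickness_left", "lam_thickness_right",
              "oim_thickness_left", "oim_thickness_right")


def default_schemas() -> tuple[LabelSchema, LabelSchema]:
    return (LabelSchema("coronal", dict(CORONAL_LABELS)),
            LabelSchema("sagittal", dict(SAGITTAL_LABELS)))


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one synthetic case; the seed and the fields
    below determine every voxel."""

    shape: tuple[int, int, int] = (160, 160, 24)
    spacing: tuple[float, float, float] = (0.63, 0.63, 3.0)
    coronal_mul_mm: float = 14.0          # typical membranous urethral length
    sagittal_mul_mm: float = 15.0
    urethra_radius_mm: float = 1.5        # urethra caliber ~2-3 mm
    urethra_curve_mm: float = 0.0         # lateral bow of the centerline
    ippl_mm: float = 2.5                  # prostatic protrusion height; 0=flat
    lam_thickness_mm: tuple[float, float] = (9.0, 9.0)    # (left, right)
    oim_thickness_mm: tuple[float, float] = (18.0, 18.0)
    muscle_rotation_deg: tuple[float, float, float, float] = (0.0, 0.0,
                                                              0.0, 0.0)
    prostate_semiaxes_mm: tuple[float, float, float] = (9.0, 15.0, 4.5)
    corpus_semiaxes_mm: tuple[float, float, float] = (8.0, 12.0, 4.5)
    bladder_semiaxes_mm: tuple[float, float] = (14.0, 28.0)
    split_gap_rows: int = 0               # urethra gap (rows) in both planes
    jitter_prob: float = 0.0              # boundary jitter; 0 keeps truth exact
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coronal_mul_mm", "sagittal_mul_mm",
                     "urethra_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ippl_mm < 0 or self.split_gap_rows < 0:
            raise ValueError("ippl_mm and split_gap_rows must be >= 0")
        if not 0.0 <= self.jitter_prob <= 0.5:
            raise ValueError("jitter_prob must be in [0, 0.5]")
        if any(t <= 0 for t in self.lam_thickness_mm + self.oim_thickness_mm):
            raise ValueError("muscle thicknesses must be positive")


@dataclass
class PhantomCase:
    coronal: LabelVolume
    sagittal: LabelVolume
    truth: dict[str, float]
    spec: PhantomSpec


# -- primitives --------------------------------------------------------------

def rasterize_tube(control_points_mm: np.ndarray, radius_mm: float,
                   shape: tuple[int, int, int],
                   spacing: tuple[float, float, float]
                   ) -> tuple[BinaryMask3D, float]:
    """Voxelize a tube around a piecewise-linear centerline.

    Control points are world-mm coordinates ordered superior to inferior
    (strictly increasing along axis 0).  A voxel belongs to the tube when its
    center lies within ``radius_mm`` of the centerline *and* its axis-0
    coordinate lies inside the centerline's span — i.e. the tube has flat
    ends, not spherical caps, so the per-row centroid polyline terminates at
    the true endpoints.  Returns the mask and the analytic centerline length.
    """
    pts = np.asarray(control_points_mm, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("need at least 2 control points")
    if not np.all(np.diff(pts[:, 0]) > 0):
        raise ValueError("control points must be strictly "
                         "superior-to-inferior along axis 0")
    spacing = np.asarray(spacing, dtype=float)
    extent = (np.asarray(shape) - 1) * spacing
    lo = pts.min(axis=0) - radius_mm
    hi = pts.max(axis=0) + radius_mm
    if np.any(np.minimum(lo, 0) < -spacing / 2) or \
            np.any(hi > extent + spacing / 2):
        raise ValueError("tube exits the grid")
    # candidate voxels: bounding box of the centerline inflated by the radius
    i0 = np.maximum(0, np.floor(lo / spacing)).astype(int)
    i1 = np.minimum(np.asarray(shape) - 1,
                    np.ceil(hi / spacing)).astype(int)
    grids = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(i0, i1)),
                        indexing="ij")
    centers = np.stack([g.ravel() * s for g, s in zip(grids, spacing)],
                       axis=1)
    dmin = np.full(len(centers), np.inf)
    for p, q in zip(pts[:-1], pts[1:]):
        seg = q - p
        t = np.clip((centers - p) @ seg / (seg @ seg), 0.0, 1.0)
        d = np.linalg.norm(centers - p - t[:, None] * seg, axis=1)
        np.minimum(dmin, d, out=dmin)
    inside = (dmin <= radius_mm) \
        & (centers[:, 0] >= pts[0, 0] - 1e-9) \
        & (centers[:, 0] <= pts[-1, 0] + 1e-9)
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(g.ravel()[inside] for g in grids)] = True
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return BinaryMask3D(mask, spacing), length


def _ellipsoid(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    coords = np.meshgrid(*(np.arange(n) * s
                           for n, s in zip(shape, spacing)), indexing="ij")
    q = sum(((c - c0) / a) ** 2
            for c, c0, a in zip(coords, center_mm, semiaxes_mm))
    # tolerance keeps apex voxels that land exactly on the boundary
    return q <= 1.0 + 1e-12


def _slab_2d(shape2d, spacing2d, center_mm, angle_deg, thickness_mm,
             length_mm) -> np.ndarray:
    """Rotated rectangular slab: |perpendicular offset| < thickness/2 and
    |along-axis offset| < length/2, angle measured from the row axis."""
    yy, xx = np.meshgrid(np.arange(shape2d[0]) * spacing2d[0],
                         np.arange(shape2d[1]) * spacing2d[1], indexing="ij")
    th = np.deg2rad(angle_deg)
    u = (np.cos(th), np.sin(th))          # along the slab
    dy, dx = yy - center_mm[0], xx - center_mm[1]
    along = dy * u[0] + dx * u[1]
    perp = -dy * u[1] + dx * u[0]
    return (np.abs(perp) < thickness_mm / 2) & (np.abs(along) < length_mm / 2)


def perturb_boundary(mask: BinaryMask3D, jitter_prob: float,
                     seed: int) -> BinaryMask3D:
    """Independently toggle off each surface voxel with probability
    *jitter_prob*; interior voxels are untouched.  Emulates rater/model
    boundary disagreement at a controlled rate."""
    if not 0.0 <= jitter_prob <= 0.5:
        raise ValueError("jitter_prob must be in [0, 0.5]")
    if jitter_prob == 0.0 or mask.is_empty:
        return BinaryMask3D(mask.data.copy(), mask.spacing)
    rng = np.random.default_rng(seed)
    surf = surface_voxels(mask.data)
    toggle = rng.random(len(surf)) < jitter_prob
    out = mask.data.copy()
    out[tuple(surf[toggle].T)] = False
    return BinaryMask3D(out, mask.spacing)


# -- scene assembly ----------------------------------------------------------

def _snap_row(y_mm: float, sy: float) -> int:
    return int(round(y_mm / sy))


def _tube_control_points(top_row: int, n_rows: int, x_center_mm: float,
                         curve_mm: float, sy: float, z_mm: float
                         ) -> np.ndarray:
    """3-point centerline with rows snapped to pixel centers; the middle
    point bows laterally by *curve_mm*."""
    mid_row = top_row + n_rows // 2
    bot_row = top_row + n_rows
    pts = [(top_row * sy, x_center_mm, z_mm)]
    if curve_mm != 0.0:
        pts.append((mid_row * sy, x_center_mm + curve_mm, z_mm))
    pts.append((bot_row * sy, x_center_mm, z_mm))
    return np.asarray(pts)


def _apply_split(tube: np.ndarray, top_row: int, n_rows: int,
                 gap_rows: int) -> np.ndarray:
    """Remove *gap_rows* rows just above the tube's midpoint, splitting it
    into a prostate-attached and a corpus-attached part."""
    if gap_rows == 0:
        return tube
    g0 = top_row + n_rows // 2 - gap_rows // 2
    out = tube.copy()
    out[g0:g0 + gap_rows] = False
    return out


def _compose(shape, structures: dict[str, np.ndarray],
             labels: dict[str, int]) -> np.ndarray:
    vol = np.zeros(shape, dtype=np.int16)
    for name, mask in structures.items():
        vol[mask & (vol == 0)] = labels[name]
    return vol


def _muscle_scene(spec: PhantomSpec, mid_k: int) -> dict[str, np.ndarray]:
    """Four slabs in slice bands clear of the prostate: OIM pair superior to
    the stack start, LAM pair near the stack end, left/right halves."""
    H, W, D = spec.shape
    sy, sx, _ = spec.spacing
    half = W * sx / 2
    y_c = H * sy / 2
    placements = {
        "oim_left": (spec.oim_thickness_mm[0], spec.muscle_rotation_deg[2],
                     (y_c, half * 0.5), range(2, 5)),
        "oim_right": (spec.oim_thickness_mm[1], spec.muscle_rotation_deg[3],
                      (y_c, half * 1.5), range(2, 5)),
        "lam_left": (spec.lam_thickness_mm[0], spec.muscle_rotation_deg[0],
                     (y_c, half * 0.5), range(D - 5, D - 2)),
        "lam_right": (spec.lam_thickness_mm[1], spec.muscle_rotation_deg[1],
                      (y_c, half * 1.5), range(D - 5, D - 2)),
    }
    out = {}
    for name, (t, angle, center, slices) in placements.items():
        plane = _slab_2d((H, W), (sy, sx), center, angle, t, t + 15.0)
        mask = np.zeros(spec.shape, dtype=bool)
        for k in slices:
            mask[:, :, k] = plane
        out[name] = mask
    return out


def _coronal_scene(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    H, W, D = spec.shape
    sy, sx, sz = spec.spacing
    mid_k = D // 2
    z_mm = mid_k * sz
    x_c = (W // 2) * sx
    n_rows = max(2, round(spec.coronal_mul_mm / sy))
    top_row = H // 2 - n_rows // 2
    pts = _tube_control_points(top_row, n_rows, x_c, spec.urethra_curve_mm,
                               sy, z_mm)
    tube, length = rasterize_tube(pts, spec.urethra_radius_mm, spec.shape,
                                  spec.spacing)
    urethra = _apply_split(tube.data, top_row, n_rows, spec.split_gap_rows)
    a_p = spec.prostate_semiaxes_mm
    prostate = _ellipsoid(spec.shape, spec.spacing,
                          ((top_row - 1) * sy - a_p[0], x_c, z_mm), a_p)
    a_c = spec.corpus_semiaxes_mm
    corpus = _ellipsoid(spec.shape, spec.spacing,
                        ((top_row + n_rows + 1) * sy + a_c[0], x_c, z_mm),
                        a_c)
    structures = {"urethra": urethra, "prostate": prostate & ~urethra,
                  "corpus_spongiosum": corpus & ~urethra}
    structures.update(_muscle_scene(spec, mid_k))
    return _compose(spec.shape, structures, CORONAL_LABELS), length


def _sagittal_scene(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    H, W, D = spec.shape
    sy, sx, sz = spec.spacing
    mid_k = D // 2
    z_mm = mid_k * sz
    x_c = (W // 2) * sx
    a_bl, b_bl = spec.bladder_semiaxes_mm
    a_p = spec.prostate_semiaxes_mm

    r0 = _snap_row(0.30 * H * sy, sy)          # prostate top / interface row
    # prostate: ellipsoid with its top clipped flat at row r0
    center_y = r0 * sy + 0.55 * a_p[0]
    prostate3d = _ellipsoid(spec.shape, spec.spacing, (center_y, x_c, z_mm),
                            a_p)
    rows = np.arange(H)
    prostate3d &= (rows >= r0)[:, None, None]
    # bladder: wide ellipsoid strictly above the interface row
    bladder3d = _ellipsoid(spec.shape, spec.spacing,
                           (r0 * sy - 0.8 * a_bl, x_c, z_mm),
                           (a_bl, b_bl, a_p[2]))
    bladder3d &= (rows <= r0 - 1)[:, None, None]
    # optional protrusion: semicircular bump through the flat interface,
    # carved out of the bladder; height above the chord row = true IPPL
    if spec.ippl_mm > 0:
        yy, xx = np.meshgrid(rows * sy, np.arange(W) * sx, indexing="ij")
        bump2d = ((yy - r0 * sy) ** 2 + (xx - x_c) ** 2
                  <= spec.ippl_mm ** 2) & (rows < r0)[:, None]
        prostate3d[:, :, mid_k] |= bump2d
        bladder3d[:, :, mid_k] &= ~bump2d

    # urethra below the prostate apex, corpus spongiosum below the urethra
    apex_row = int(np.nonzero(prostate3d[:, W // 2, mid_k])[0].max())
    n_rows = max(2, round(spec.sagittal_mul_mm / sy))
    pts = _tube_control_points(apex_row + 1, n_rows, x_c,
                               spec.urethra_curve_mm, sy, z_mm)
    tube, length = rasterize_tube(pts, spec.urethra_radius_mm, spec.shape,
                                  spec.spacing)
    urethra = _apply_split(tube.data, apex_row + 1, n_rows,
                           spec.split_gap_rows)
    a_c = spec.corpus_semiaxes_mm
    corpus = _ellipsoid(spec.shape, spec.spacing,
                        ((apex_row + n_rows + 2) * sy + a_c[0], x_c, z_mm),
                        a_c)
    structures = {"urethra": urethra, "prostate": prostate3d & ~urethra,
                  "bladder": bladder3d,
                  "corpus_spongiosum": corpus & ~urethra}
    return _compose(spec.shape, structures, SAGITTAL_LABELS), length


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build one synthetic case: coronal + sagittal label volumes and the
    analytic truth for every measurement.  Bit-reproducible from the spec."""
    coronal_vox, cor_len = _coronal_scene(spec)
    sagittal_vox, sag_len = _sagittal_scene(spec)
    cor_schema, sag_schema = default_schemas()
    spacing = np.asarray(spec.spacing, dtype=float)
    if spec.jitter_prob > 0:
        rng = np.random.default_rng(spec.seed)
        for vox, labels in ((coronal_vox, CORONAL_LABELS),
                            (sagittal_vox, SAGITTAL_LABELS)):
            for name, label in labels.items():
                sub_seed = int(rng.integers(0, 2 ** 31))
                m = perturb_boundary(BinaryMask3D(vox == label, spacing),
                                     spec.jitter_prob, sub_seed)
                vox[(vox == label) & ~m.data] = 0
    affine = np.diag([*spec.spacing, 1.0])
    truth = {
        "coronal_mul": cor_len,
        "sagittal_mul": sag_len,
        "ippl": spec.ippl_mm,
        "lam_thickness_left": spec.lam_thickness_mm[0],
        "lam_thickness_right": spec.lam_thickness_mm[1],
        "oim_thickness_left": spec.oim_thickness_mm[0],
        "oim_thickness_right": spec.oim_thickness_mm[1],
        "lam_thickness": max(spec.lam_thickness_mm),
        "oim_thickness": max(spec.oim_thickness_mm),
    }
    return PhantomCase(
        coronal=LabelVolume(coronal_vox, affine, cor_schema),
        sagittal=LabelVolume(sagittal_vox, affine, sag_schema),
        truth=truth, spec=spec)


def random_spec(seed: int, *, split: bool = False,
                spacing: tuple[float, float, float] = (0.63, 0.63, 3.0)
                ) -> PhantomSpec:
    """Randomized spec spanning clinically plausible magnitudes:
    MUL in [8, 22] mm, IPPL in [0, 8] mm (one case in four exactly flat),
    muscle thickness in [5, 25] mm, slab rotations in {0, 30, 60} degrees."""
    rng = np.random.default_rng(seed)
    ippl = 0.0 if rng.random() < 0.25 else float(rng.uniform(0.5, 8.0))
    return PhantomSpec(
        spacing=spacing,
        coronal_mul_mm=float(rng.uniform(8.0, 22.0)),
        sagittal_mul_mm=float(rng.uniform(8.0, 22.0)),
        urethra_curve_mm=float(rng.uniform(0.0, 1.5)),
        ippl_mm=ippl,
        lam_thickness_mm=tuple(rng.uniform(5.0, 25.0, 2).round(2)),
        oim_thickness_mm=tuple(rng.uniform(5.0, 25.0, 2).round(2)),
        muscle_rotation_deg=tuple(rng.choice([0.0, 30.0, 60.0], 4)),
        split_gap_rows=2 if split else 0,
        seed=seed)
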