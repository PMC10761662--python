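"""Automated pelvic measurement algorithms on 2D/3D binary masks.

Four measurements are implemented, all reported in millimetres (world space):

* **MUL** (membranous urethral length), coronal and sagittal: on the largest
  in-plane slice of the urethra mask, the per-row centroids form a polyline
  running superior to inferior; the MUL is its arc length.  When the urethra
  splits into two components (one attached to the prostate apex, one to the
  corpus spongiosum), both parts contribute and the gap between the facing
  endpoints is, by default, bridged with a straight segment.
* **IPPL** (intravesical prostatic protrusion length): the bladder-prostate
  interface is found by a one-pixel dilation of the bladder; a chord connects
  the two outermost interface points and the IPPL is the maximum perpendicular
  distance from that chord to prostate contour points on the bladder side.
* **Muscle thickness** (levator ani, obturator internus): per in-plane slice,
  the distances from the medial-axis centerline to the muscle border are
  collected (anisotropy-aware Euclidean distance transform in mm); the
  maximum is doubled to give the muscle diameter.

No sub-voxel refinement is performed anywhere; tolerances in the validation
suite are stated in voxel units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import medial_axis

from .label_volumes import (
    BinaryMask2D,
    BinaryMask3D,
    LabelVolume,
    SchemaError,
    connected_components_2d,
    extract_structure_mask,
    select_measurement_slice,
)

logger = logging.getLogger("pelvimetry")


@dataclass
class Polyline:
    """Ordered 2D points in mm, one per occupied image row, superior first."""

    points: np.ndarray          # (n, 2) as (row_mm, col_mm)
    rows: np.ndarray            # (n,) source row indices, strictly increasing

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.rows = np.asarray(self.rows, dtype=int).reshape(-1)
        if len(self.points) < 1:
            raise ValueError("polyline needs at least one point")
        if len(self.rows) > 1 and not np.all(np.diff(self.rows) > 0):
            raise ValueError("polyline rows must strictly increase")


@dataclass
class MULResult:
    length_mm: float
    n_components_used: int
    component_lengths_mm: list[float]
    bridge_length_mm: float
    slice_index: int
    plane: str
    flags: tuple[str, ...] = ()
    polylines: list[Polyline] = field(default_factory=list)


@dataclass
class IPPLResult:
    ippl_mm: float
    interface_points: np.ndarray                  # (m, 2) in mm
    chord_endpoints: np.ndarray | None = None     # (2, 2) in mm
    argmax_contour_point: np.ndarray | None = None
    flags: tuple[str, ...] = ()


@dataclass
class ThicknessResult:
    thickness_mm: float
    side: str
    slice_index_of_max: int
    centerline_point_of_max: np.ndarray           # (2,) in mm
    flags: tuple[str, ...] = ()


@dataclass
class MeasurementResult:
    """One named pelvic parameter with provenance for overlay rendering."""

    name: str
    plane: str
    value_mm: float
    flags: tuple[str, ...] = ()
    n_components: int | None = None
    provenance: dict = field(default_factory=dict)


def row_centroid_polyline(component: BinaryMask2D) -> Polyline:
    """Per-row centroids of a component, superior to inferior.

    Axis 0 of the mask is the superior-inferior direction.  For each occupied
    row the centroid is the mean physical position of its true pixels; rows
    inside the component's span with no pixels are skipped and logged.
    """
    if component.is_empty:
        raise ValueError("cannot build a centroid polyline of an empty mask")
    sy, sx = component.spacing
    rr, cc = np.nonzero(component.data)
    rows = np.unique(rr)
    gaps = np.setdiff1d(np.arange(rows[0], rows[-1] + 1), rows)
    if gaps.size:
        logger.warning("WARN rows %s inside component span have no pixels; "
                       "skipped", gaps.tolist())
    pts = np.empty((rows.size, 2))
    for i, r in enumerate(rows):
        pts[i] = (r * sy, cc[rr == r].mean() * sx)
    return Polyline(points=pts, rows=rows)


def polyline_length(polyline: Polyline) -> float:
    """Arc length in mm: sum of consecutive Euclidean distances."""
    if len(polyline.points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(polyline.points, axis=0),
                                axis=1).sum())


def measure_mul(urethra_slice: BinaryMask2D, *, plane: str = "coronal",
                max_components: int = 2, bridge: str = "include",
                connectivity: int = 8) -> MULResult:
    """Membranous urethral length on one in-plane slice.

    One component: arc length of its centroid polyline.  Two or more: the two
    largest are kept (extras logged and ignored); the superior component is
    the one whose topmost row is smaller.  Under the default ``include``
    bridge policy the straight-line distance between the inferior endpoint of
    the superior part and the superior endpoint of the inferior part is added,
    treating the urethra as anatomically continuous; ``exclude`` reports the
    sum of the part lengths only.  An empty mask yields length 0 with a flag.
    """
    if bridge not in ("include", "exclude"):
        raise ValueError("bridge policy must be 'include' or 'exclude'")
    flags = tuple(urethra_slice.flags)
    if urethra_slice.is_empty:
        return MULResult(0.0, 0, [], 0.0, urethra_slice.slice_index, plane,
                         flags=flags + ("empty_mask",))
    comps = connected_components_2d(urethra_slice, connectivity=connectivity)
    if len(comps) > max_components:
        dropped = [c.count for c in comps[max_components:]]
        logger.warning("WARN %d extra urethra component(s) of sizes %s "
                       "ignored", len(dropped), dropped)
        flags += ("components_dropped",)
    used = comps[:max_components]
    polylines = [row_centroid_polyline(c) for c in used]
    lengths = [polyline_length(p) for p in polylines]
    bridge_mm = 0.0
    if len(used) == 2:
        # order the two parts superior -> inferior by topmost row
        order = np.argsort([p.rows[0] for p in polylines])
        polylines = [polylines[i] for i in order]
        lengths = [lengths[i] for i in order]
        gap = float(np.linalg.norm(polylines[0].points[-1]
                                   - polylines[1].points[0]))
        if bridge == "include":
            bridge_mm = gap
            logger.warning("WARN split urethra: bridging %.2f mm gap between "
                           "components", gap)
        else:
            flags += ("bridge_excluded",)
            logger.warning("WARN split urethra: %.2f mm gap excluded by "
                           "policy", gap)
    return MULResult(length_mm=float(sum(lengths) + bridge_mm),
                     n_components_used=len(used),
                     component_lengths_mm=[float(v) for v in lengths],
                     bridge_length_mm=bridge_mm,
                     slice_index=urethra_slice.slice_index,
                     plane=plane, flags=flags, polylines=polylines)


_CROSS_2D = ndimage.generate_binary_structure(2, 1)   # 4-connected cross
_FULL_2D = ndimage.generate_binary_structure(2, 2)    # 8-connected square


def prostate_bladder_interface(bladder: BinaryMask2D, prostate: BinaryMask2D,
                               connectivity: int = 4) -> np.ndarray:
    """Physical coordinates (mm) of prostate pixels touching the bladder.

    The interface is the intersection of the prostate with a one-pixel
    dilation of the bladder.  The structuring element defaults to the
    4-connected cross (a diagonal-only contact therefore yields no
    interface); 8-connectivity is available as a config choice.
    """
    if bladder.data.shape != prostate.data.shape:
        raise ValueError("bladder and prostate masks must share a shape")
    elem = _CROSS_2D if connectivity == 4 else _FULL_2D
    dilated = ndimage.binary_dilation(bladder.data, structure=elem)
    contact = dilated & prostate.data
    return np.argwhere(contact) * prostate.spacing


def _chord_endpoints(points_mm: np.ndarray) -> np.ndarray:
    """Outermost pair (max pairwise distance); ties pick the
    lexicographically smallest coordinate pair."""
    d2 = ((points_mm[:, None, :] - points_mm[None, :, :]) ** 2).sum(-1)
    best = -1.0
    pair = (0, 0)
    m = len(points_mm)
    for i in range(m):
        for j in range(i, m):
            if d2[i, j] > best + 1e-12:
                best, pair = d2[i, j], (i, j)
            elif abs(d2[i, j] - best) <= 1e-12:
                cand = sorted([tuple(points_mm[i]), tuple(points_mm[j])])
                cur = sorted([tuple(points_mm[pair[0]]),
                              tuple(points_mm[pair[1]])])
                if cand < cur:
                    pair = (i, j)
                    logger.warning("WARN chord-endpoint tie; keeping "
                                   "lexicographically smallest pair")
    return np.array([points_mm[pair[0]], points_mm[pair[1]]])


def measure_ippl(bladder: BinaryMask2D, prostate: BinaryMask2D,
                 dilation_connectivity: int = 4) -> IPPLResult:
    """Intravesical prostatic protrusion length on one sagittal slice.

    A chord joins the two outermost bladder-prostate interface points.  The
    protrusion is the maximum perpendicular distance from the chord to the
    prostate contour (8-boundary pixels), restricted to contour points
    strictly on the bladder side of the chord; which side is "bladder" is
    decided by the sign of the bladder centroid's perpendicular offset.
    Returns 0 when the structures do not touch or nothing protrudes.
    """
    flags = tuple(dict.fromkeys(bladder.flags + prostate.flags))
    interface = prostate_bladder_interface(bladder, prostate,
                                           connectivity=dilation_connectivity)
    if len(interface) == 0:
        return IPPLResult(0.0, interface, flags=flags + ("no_interface",))
    chord = _chord_endpoints(interface)
    p0, p1 = chord
    d = p1 - p0
    norm = float(np.linalg.norm(d))
    if norm == 0.0:  # single-point interface: no chord direction
        return IPPLResult(0.0, interface, chord_endpoints=chord,
                          flags=flags + ("degenerate_chord",))

    def signed_dist(pts: np.ndarray) -> np.ndarray:
        rel = pts - p0
        return (d[0] * rel[:, 1] - d[1] * rel[:, 0]) / norm

    bl_centroid = np.argwhere(bladder.data).mean(axis=0) * bladder.spacing
    side = float(signed_dist(bl_centroid[None, :])[0])
    if side == 0.0:
        return IPPLResult(0.0, interface, chord_endpoints=chord,
                          flags=flags + ("ambiguous_bladder_side",))
    boundary = prostate.data & ~ndimage.binary_erosion(
        prostate.data, structure=_FULL_2D, border_value=0)
    contour = np.argwhere(boundary) * prostate.spacing
    s = signed_dist(contour)
    candidates = s * np.sign(side) > 0
    if not candidates.any():
        return IPPLResult(0.0, interface, chord_endpoints=chord, flags=flags)
    dists = np.abs(s[candidates])
    k = int(np.argmax(dists))
    return IPPLResult(float(dists[k]), interface, chord_endpoints=chord,
                      argmax_contour_point=contour[candidates][k],
                      flags=flags)


def measure_muscle_thickness(muscle: BinaryMask3D, side: str = "combined_max",
                             in_plane_axes: tuple[int, int] = (0, 1)
                             ) -> ThicknessResult:
    """Maximum muscle diameter: 2x the largest centerline-to-border distance.

    Each in-plane 2D slice containing muscle pixels is processed
    independently: the medial-axis centerline is computed and the Euclidean
    distance transform to the background (in mm, anisotropy-aware) is sampled
    at centerline points.  The overall maximum, doubled, is the thickness.
    Through-plane distances are deliberately not used: with 3.0-3.5 mm slices
    they are unreliable compared to sub-millimetre in-plane spacing.
    """
    if muscle.is_empty:
        raise ValueError("cannot measure thickness of an empty muscle mask")
    through_axis = ({0, 1, 2} - set(in_plane_axes)).pop()
    spacing2d = muscle.spacing[list(in_plane_axes)]
    best = (-1.0, -1, np.zeros(2))
    for k in range(muscle.data.shape[through_axis]):
        plane = np.take(muscle.data, k, axis=through_axis)
        if not plane.any():
            continue
        edt = ndimage.distance_transform_edt(plane, sampling=spacing2d)
        skel = medial_axis(plane)
        vals = edt[skel]
        if vals.size == 0:
            continue
        i = int(np.argmax(vals))
        if vals[i] > best[0]:
            pt = np.argwhere(skel)[i] * spacing2d
            best = (float(vals[i]), k, pt)
    return ThicknessResult(thickness_mm=2.0 * best[0], side=side,
                           slice_index_of_max=best[1],
                           centerline_point_of_max=best[2])


_MISSING = float("nan")


def _flagged(name: str, plane: str, reason: str) -> MeasurementResult:
    logger.warning("WARN %s (%s) unavailable: %s", name, plane, reason)
    return MeasurementResult(name=name, plane=plane, value_mm=_MISSING,
                             flags=(reason,))


def _mul_measurement(vol: LabelVolume, name: str, plane: str,
                     bridge: str, through_axis: int) -> MeasurementResult:
    try:
        mask = extract_structure_mask(vol, "urethra")
    except SchemaError:
        return _flagged(name, plane, "missing_structure:urethra")
    sl = select_measurement_slice(mask, through_axis=through_axis)
    res = measure_mul(sl, plane=plane, bridge=bridge)
    return MeasurementResult(
        name=name, plane=plane, value_mm=res.length_mm, flags=res.flags,
        n_components=res.n_components_used,
        provenance={"slice_index": res.slice_index,
                    "component_lengths_mm": res.component_lengths_mm,
                    "bridge_length_mm": res.bridge_length_mm,
                    "polylines": [p.points.tolist() for p in res.polylines]})


def _thickness_measurement(vol: LabelVolume, structure_base: str, name: str
                           ) -> list[MeasurementResult]:
    out: list[MeasurementResult] = []
    per_side: dict[str, float] = {}
    for side in ("left", "right"):
        structure = f"{structure_base}_{side}"
        try:
            mask = extract_structure_mask(vol, structure)
            if mask.is_empty:
                out.append(_flagged(f"{name}_{side}", "coronal",
                                    "empty_mask"))
                continue
            res = measure_muscle_thickness(mask, side=side)
        except SchemaError:
            out.append(_flagged(f"{name}_{side}", "coronal",
                                f"missing_structure:{structure}"))
            continue
        per_side[side] = res.thickness_mm
        out.append(MeasurementResult(
            name=f"{name}_{side}", plane="coronal", value_mm=res.thickness_mm,
            provenance={"slice_index_of_max": res.slice_index_of_max,
                        "centerline_point_of_max":
                            res.centerline_point_of_max.tolist()}))
    if per_side:
        out.append(MeasurementResult(name=name, plane="coronal",
                                     value_mm=max(per_side.values()),
                                     provenance={"combined": "max",
                                                 "sides": per_side}))
    else:
        out.append(_flagged(name, "coronal", "no_side_available"))
    return out


def measure_all(coronal: LabelVolume, sagittal: LabelVolume, *,
                mul_bridge: str = "include", dilation_connectivity: int = 4,
                through_axis: int = 2) -> list[MeasurementResult]:
    """Run the full automated measurement workflow on one case.

    Coronal MUL and the LAM/OIM thicknesses come from the coronal volume;
    sagittal MUL and the IPPL from the sagittal volume (the bladder is only
    delineated sagittally).  A missing or empty structure produces a flagged
    result rather than an exception, so one bad structure never aborts a
    batch.
    """
    results = [
        _mul_measurement(coronal, "coronal_mul", "coronal", mul_bridge,
                         through_axis),
        _mul_measurement(sagittal, "sagittal_mul", "sagittal", mul_bridge,
                         through_axis),
    ]
    # IPPL on the sagittal slice where the prostate is largest
    try:
        bladder = extract_structure_mask(sagittal, "bladder")
        prostate = extract_structure_mask(sagittal, "prostate")
        if bladder.is_empty or prostate.is_empty:
            results.append(_flagged("ippl", "sagittal", "empty_mask"))
        else:
            prostate_sl = select_measurement_slice(prostate,
                                                   through_axis=through_axis)
            k = prostate_sl.slice_index
            bladder_sl = BinaryMask2D(
                np.take(bladder.data, k, axis=through_axis),
                prostate_sl.spacing, slice_index=k)
            res = measure_ippl(bladder_sl, prostate_sl,
                               dilation_connectivity=dilation_connectivity)
            results.append(MeasurementResult(
                name="ippl", plane="sagittal", value_mm=res.ippl_mm,
                flags=res.flags,
                provenance={"slice_index": k,
                            "chord_endpoints":
                                None if res.chord_endpoints is None
                                else res.chord_endpoints.tolist(),
                            "argmax_contour_point":
                                None if res.argmax_contour_point is None
                                else res.argmax_contour_point.tolist()}))
    except SchemaError as exc:
        results.append(_flagged("ippl", "sagittal", f"schema:{exc}"))
    results.extend(_thickness_measurement(coronal, "lam", "lam_thickness"))
    results.extend(_thickness_measurement(coronal, "oim", "oim_thickness"))
    return results
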