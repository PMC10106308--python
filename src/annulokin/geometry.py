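"""Per-frame 3D geometry of the mitral annulus from an ordered crystal ring.

The annulus is reconstructed from eight transducer ("crystal") positions by a
closed periodic cubic spline, projected onto its least-squares plane, and
summarised by five scalar metrics:

``MAA``
    mitral annular area (mm^2): shoelace area of the projected spline.
``ICW``
    intercommissural width (mm): 3D distance between the two annular points
    where the spline crosses the first principal axis of the projected curve.
``SL``
    septolateral diameter (mm): same for the second principal axis; its
    endpoints are the anterior and posterior saddle horns (AH, PH).
``ACI``
    annular circularity index, SL/ICW (1 = circular, <1 = elliptic).
``NPA``
    non-planarity angle (degrees): angle subtended by AH and PH at the
    juncture of the SL and ICW axes (180 deg = flat annulus, smaller = more
    saddle-shaped).

All operations are invariant under rigid motion of the input coordinates, and
behave equivariantly under uniform scaling (MAA ~ s^2, SL/ICW ~ s, ACI and
NPA fixed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import LinearRing

__all__ = [
    "MIN_POINT_SEPARATION_MM",
    "GeometryError",
    "DegenerateGeometryError",
    "DegeneracyWarning",
    "SelfIntersectionWarning",
    "AnnulusFrame",
    "AnnulusSpline",
    "FittedPlane",
    "PrincipalAxes",
    "AreaResult",
    "GeometryFrame",
    "fit_closed_spline",
    "fit_plane_and_project",
    "spline_area",
    "principal_axes",
    "axis_intersections",
    "compute_dimensions_and_aci",
    "compute_npa",
    "juncture_point",
    "analyze_frame",
    "analyze_trajectory",
    "geometry_table",
]

#: minimum allowed spacing (mm) between consecutive crystals around the ring
MIN_POINT_SEPARATION_MM = 0.01


class GeometryError(ValueError):
    """Invalid input to a geometric operation."""


class DegenerateGeometryError(GeometryError):
    """Configuration without a unique geometric solution."""


class DegeneracyWarning(UserWarning):
    """Nearly isotropic curve: principal axes resolved by a tie-break."""


class SelfIntersectionWarning(UserWarning):
    """Projected annular curve crosses itself; area is |signed area|."""


@dataclass(frozen=True)
class AnnulusFrame:
    """Eight anatomically ordered annular crystal positions at one instant.

    Parameters
    ----------
    points : (8, 3) array
        Crystal coordinates in mm, ordered circularly around the annulus
        (point 8 is adjacent to point 1).
    time : float
        Acquisition time in seconds.
    """

    points: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (8, 3):
            raise GeometryError(f"expected 8 points with 3 coordinates, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("non-finite crystal coordinate")
        gaps = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        if np.any(gaps <= MIN_POINT_SEPARATION_MM):
            raise GeometryError(
                "coincident consecutive crystals (separation <= "
                f"{MIN_POINT_SEPARATION_MM} mm at position {int(np.argmin(gaps)) + 1})"
            )
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class AnnulusSpline:
    """Closed interpolating cubic curve through the crystal ring.

    ``samples`` are ``M`` points on the curve at parameters ``knot_params``
    (uniform on [0, 1)); ``spline`` is the underlying periodic interpolant
    and ``knot_sites`` the chord-length parameters of the eight crystals.
    """

    samples: np.ndarray
    knot_params: np.ndarray
    spline: CubicSpline = field(repr=False)
    knot_sites: np.ndarray = field(repr=False)

    def __call__(self, u: float | np.ndarray, nu: int = 0) -> np.ndarray:
        return self.spline(np.asarray(u) % 1.0, nu=nu)


@dataclass(frozen=True)
class FittedPlane:
    """Least-squares plane with an in-plane orthonormal basis.

    ``normal`` has unit length; ``basis_u``/``basis_v`` span the plane and
    (basis_u, basis_v, normal) is right-handed.
    """

    centroid: np.ndarray
    normal: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray

    def project(self, points: np.ndarray) -> np.ndarray:
        """In-plane 2D coordinates of ``points`` (orthogonal projection)."""
        rel = np.atleast_2d(points) - self.centroid
        return rel @ np.stack([self.basis_u, self.basis_v], axis=1)


class PrincipalAxes(NamedTuple):
    axis1: np.ndarray  # in-plane unit vector of largest variance (intercommissural)
    axis2: np.ndarray  # orthogonal unit vector (septolateral)
    degenerate: bool


class AreaResult(NamedTuple):
    area: float
    self_intersecting: bool


@dataclass(frozen=True)
class GeometryFrame:
    """All annular metrics for one time sample."""

    MAA: float
    SL: float
    ICW: float
    ACI: float
    NPA: float
    plane: FittedPlane
    AH: np.ndarray
    PH: np.ndarray
    ALC: np.ndarray
    PMC: np.ndarray
    time: float = 0.0
    axes: PrincipalAxes | None = None
    flag_degenerate: bool = False
    flag_selfintersect: bool = False


# ---------------------------------------------------------------------------
# spline reconstruction


def fit_closed_spline(frame: AnnulusFrame, n_samples: int = 360) -> AnnulusSpline:
    """Closed periodic cubic spline through the eight crystals.

    Chord-length parameterisation (rotation invariant); the curve is C2 across
    the seam and interpolates every crystal exactly.
    """
    if n_samples < 64:
        raise GeometryError(f"n_samples must be >= 64, got {n_samples}")
    pts = frame.points
    closed = np.vstack([pts, pts[:1]])
    chords = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chords)])
    t /= t[-1]
    spline = CubicSpline(t, closed, bc_type="periodic", axis=0)
    u = np.linspace(0.0, 1.0, n_samples, endpoint=False)
    return AnnulusSpline(samples=spline(u), knot_params=u, spline=spline, knot_sites=t[:-1])


# ---------------------------------------------------------------------------
# plane fitting and projection


def fit_plane_and_project(
    spline: AnnulusSpline, prev_normal: np.ndarray | None = None
) -> tuple[FittedPlane, np.ndarray]:
    """Least-squares plane of the curve samples and their 2D projection.

    The plane minimises the sum of squared orthogonal distances (total least
    squares via SVD).  The normal is oriented towards ``prev_normal`` when
    given (temporal continuity), otherwise towards +z.
    """
    X = spline.samples
    centroid = X.mean(axis=0)
    Xc = X - centroid
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("curve samples are collinear; plane is not unique")
    normal = vt[2]
    ref = np.asarray(prev_normal, dtype=float) if prev_normal is not None else np.array([0.0, 0.0, 1.0])
    d = float(normal @ ref)
    if d < 0.0 or (d == 0.0 and normal[np.nonzero(normal)[0][0]] < 0.0):
        normal = -normal
    basis_u = vt[0]
    basis_v = np.cross(normal, basis_u)
    plane = FittedPlane(centroid=centroid, normal=normal, basis_u=basis_u, basis_v=basis_v)
    return plane, Xc @ np.stack([basis_u, basis_v], axis=1)


# ---------------------------------------------------------------------------
# area


def spline_area(curve2d: np.ndarray) -> AreaResult:
    """Shoelace (surveyor) area of the densely sampled closed 2D curve.

    A self-intersecting projection is flagged with a warning and the
    magnitude of the signed area is returned rather than raising.
    """
    curve2d = np.asarray(curve2d, dtype=float)
    if curve2d.ndim != 2 or curve2d.shape[1] != 2 or curve2d.shape[0] < 3:
        raise GeometryError("curve must be an (M, 2) array with M >= 3")
    x, y = curve2d[:, 0], curve2d[:, 1]
    signed = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    self_intersecting = False
    try:
        if not LinearRing(curve2d).is_simple:
            self_intersecting = True
    except Exception:
        # degenerate (e.g. fully collinear) ring: zero area, not an error
        self_intersecting = abs(signed) > 0.0
    if self_intersecting:
        warnings.warn(
            "projected annular curve is self-intersecting; reporting |signed area|",
            SelfIntersectionWarning,
            stacklevel=2,
        )
    return AreaResult(area=abs(signed), self_intersecting=self_intersecting)


# ---------------------------------------------------------------------------
# principal axes


def _fix_sign(v: np.ndarray) -> np.ndarray:
    if v[0] < 0.0 or (v[0] == 0.0 and v[1] < 0.0):
        return -v
    return v


def principal_axes(
    curve2d: np.ndarray,
    prev_axes: PrincipalAxes | None = None,
    rel_tol: float = 1e-6,
) -> PrincipalAxes:
    """PCA axes of the projected curve samples.

    ``axis1`` carries the largest variance and is designated intercommissural;
    ``axis2`` is orthogonal (septolateral).  Signs follow a deterministic
    convention (first non-zero component non-negative).  For a nearly
    isotropic (circular) curve the eigenvalue gap vanishes; the previous
    frame's axes are kept when available (temporal continuity), otherwise the
    coordinate axes are used, and the degeneracy flag is set.
    """
    c = np.asarray(curve2d, dtype=float)
    c = c - c.mean(axis=0)
    if c.shape[0] < 3:
        raise GeometryError("need at least 3 samples for principal axes")
    cov = c.T @ c / c.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 0.0:
        raise DegenerateGeometryError("projected curve has no planar extent")
    if (evals[1] - evals[0]) < rel_tol * evals[1]:
        warnings.warn(
            "near-isotropic annular projection: principal axes are ill-defined",
            DegeneracyWarning,
            stacklevel=2,
        )
        if prev_axes is not None:
            return PrincipalAxes(prev_axes.axis1, prev_axes.axis2, True)
        return PrincipalAxes(np.array([1.0, 0.0]), np.array([0.0, 1.0]), True)
    axis1 = _fix_sign(evecs[:, 1].copy())
    axis2 = _fix_sign(np.array([-axis1[1], axis1[0]]))
    return PrincipalAxes(axis1, axis2, False)


# ---------------------------------------------------------------------------
# axis intersections and dimensions


def axis_intersections(
    spline: AnnulusSpline, plane: FittedPlane, axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """The two 3D annular points where the projected curve crosses an axis.

    The axis is an in-plane unit 2-vector; its line runs through the in-plane
    centroid.  Crossings are located on the dense sample polygon and refined
    by linear interpolation between the bracketing samples; exactly two
    crossings (one on each side of the centroid) are required.
    """
    axis = np.asarray(axis, dtype=float)
    curve2d = plane.project(spline.samples)
    perp = np.array([-axis[1], axis[0]])
    s = curve2d @ perp
    neg = s < 0.0
    cross = neg != np.roll(neg, -1)
    idx = np.nonzero(cross)[0]
    if idx.size != 2:
        raise DegenerateGeometryError(
            f"expected exactly 2 axis crossings, found {idx.size} (folded or open projection)"
        )
    pts3d = []
    along = []
    M = spline.samples.shape[0]
    for i in idx:
        j = (i + 1) % M
        f = s[i] / (s[i] - s[j])
        p3 = (1.0 - f) * spline.samples[i] + f * spline.samples[j]
        p2 = (1.0 - f) * curve2d[i] + f * curve2d[j]
        pts3d.append(p3)
        along.append(float(p2 @ axis))
    if not (min(along) < 0.0 < max(along)):
        raise DegenerateGeometryError("axis crossings do not straddle the centroid")
    order = np.argsort(along)[::-1]  # positive side first
    return pts3d[order[0]], pts3d[order[1]]


def compute_dimensions_and_aci(
    spline: AnnulusSpline, plane: FittedPlane, axes: PrincipalAxes
) -> tuple[float, float, float, dict[str, np.ndarray]]:
    """ICW, SL and their ratio ACI = SL/ICW.

    Diameters are 3D Euclidean distances between the identified annular
    points (the points live on the annulus, not in the plane).  Returns the
    landmark points as well: ALC/PMC on the intercommissural axis, AH/PH on
    the septolateral axis.
    """
    alc, pmc = axis_intersections(spline, plane, axes.axis1)
    ah, ph = axis_intersections(spline, plane, axes.axis2)
    icw = float(np.linalg.norm(alc - pmc))
    sl = float(np.linalg.norm(ah - ph))
    if icw <= 0.0:
        raise DegenerateGeometryError("zero intercommissural width")
    return icw, sl, sl / icw, {"AH": ah, "PH": ph, "ALC": alc, "PMC": pmc}


def juncture_point(
    ah: np.ndarray, ph: np.ndarray, alc: np.ndarray, pmc: np.ndarray
) -> np.ndarray:
    """Juncture of the SL and ICW axes.

    The two 3D axis lines (AH-PH and ALC-PMC) are generally skew for a
    saddle-shaped annulus; the juncture is taken as the midpoint of their
    common perpendicular, which reduces to the exact in-plane intersection
    for a planar annulus.
    """
    d1 = ph - ah
    d2 = pmc - alc
    r = alc - ah
    a = float(d1 @ d1)
    b = float(d1 @ d2)
    c = float(d2 @ d2)
    d = float(d1 @ r)
    e = float(d2 @ r)
    denom = a * c - b * b
    if denom <= 1e-12 * max(a * c, 1.0):
        # parallel axis lines: fall back to mean of the four landmarks
        return (ah + ph + alc + pmc) / 4.0
    s = (c * d - b * e) / denom
    t = (b * d - a * e) / denom
    p1 = ah + s * d1
    p2 = alc + t * d2
    return 0.5 * (p1 + p2)


def compute_npa(ah: np.ndarray, ph: np.ndarray, juncture: np.ndarray) -> float:
    """Non-planarity angle (degrees) subtended by the horns at the juncture.

    Angle between (AH - juncture) and (PH - juncture), in (0, 180]; 180 deg
    corresponds to a perfectly flat annulus.
    """
    u = np.asarray(ah, dtype=float) - juncture
    v = np.asarray(ph, dtype=float) - juncture
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= 1e-12 or nv <= 1e-12:
        raise GeometryError("horn coincides with the axis juncture; NPA undefined")
    cosang = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# composite


def analyze_frame(
    frame: AnnulusFrame,
    n_samples: int = 360,
    prev: GeometryFrame | None = None,
) -> GeometryFrame:
    """Full per-frame analysis: spline -> plane -> area -> axes -> metrics."""

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GeometryError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    spline = _stage("spline", fit_closed_spline, frame, n_samples)
    prev_normal = prev.plane.normal if prev is not None else None
    plane, curve2d = _stage("plane", fit_plane_and_project, spline, prev_normal)
    area, self_intersecting = _stage("area", spline_area, curve2d)
    prev_axes = prev.axes if prev is not None else None
    axes = _stage("pca", principal_axes, curve2d, prev_axes)
    icw, sl, aci, landmarks = _stage("dimensions", compute_dimensions_and_aci, spline, plane, axes)
    junct = juncture_point(landmarks["AH"], landmarks["PH"], landmarks["ALC"], landmarks["PMC"])
    npa = _stage("npa", compute_npa, landmarks["AH"], landmarks["PH"], junct)
    return GeometryFrame(
        MAA=area,
        SL=sl,
        ICW=icw,
        ACI=aci,
        NPA=npa,
        plane=plane,
        AH=landmarks["AH"],
        PH=landmarks["PH"],
        ALC=landmarks["ALC"],
        PMC=landmarks["PMC"],
        time=frame.time,
        axes=axes,
        flag_degenerate=axes.degenerate,
        flag_selfintersect=self_intersecting,
    )


def analyze_trajectory(
    times: Sequence[float], coords: np.ndarray, n_samples: int = 360
) -> list[GeometryFrame]:
    """Analyse a (T, 8, 3) crystal trajectory, frame by frame.

    Plane-normal orientation and degenerate-axis tie-breaks are chained from
    frame to frame for temporal stability.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[1:] != (8, 3):
        raise GeometryError(f"expected (T, 8, 3) coordinates, got {coords.shape}")
    frames: list[GeometryFrame] = []
    prev: GeometryFrame | None = None
    for t, pts in zip(times, coords):
        gf = analyze_frame(AnnulusFrame(points=pts, time=float(t)), n_samples=n_samples, prev=prev)
        frames.append(gf)
        prev = gf
    return frames


def geometry_table(frames: Sequence[GeometryFrame]):
    """Per-frame metrics as a pandas DataFrame (the geometry CSV dialect)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time_s": [f.time for f in frames],
            "MAA_mm2": [f.MAA for f in frames],
            "SL_mm": [f.SL for f in frames],
            "ICW_mm": [f.ICW for f in frames],
            "ACI": [f.ACI for f in frames],
            "NPA_deg": [f.NPA for f in frames],
            "flag_degenerate": [f.flag_degenerate for f in frames],
            "flag_selfintersect": [f.flag_selfintersect for f in frames],
        }
    )
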