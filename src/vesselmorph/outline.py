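"""Profile and outline processing for axisymmetric vessels.

A *profile* is the right half of a vessel's cross-section: ordered
``(x, y)`` points with ``x`` the radial distance from the rotation axis
(cm, nonnegative) and ``y`` the height (cm), running from the base to the
rim.  Profiles digitised from video frames arrive in pixels and are
calibrated, resampled to a fixed number of points at regular height
intervals, smoothed with a zero-phase low-pass filter, and finally
mirrored across the rotation axis into a closed full *outline* suitable
for elliptical Fourier analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Profile",
    "Outline",
    "Calibration",
    "CalibrationError",
    "GeometryError",
    "calibrate",
    "resample_profile",
    "smooth_profile",
    "mirror_to_outline",
    "profile_pipeline",
]


class CalibrationError(ValueError):
    """Raised for nonpositive pixel-to-cm conversion factors."""


class GeometryError(ValueError):
    """Raised for degenerate or unsupported profile/outline geometry."""


@dataclass(frozen=True)
class Profile:
    """Right-half cross-section of an axisymmetric object, base to rim.

    Parameters
    ----------
    x : ndarray
        Radial coordinates (cm), ``x >= 0``.
    y : ndarray
        Height coordinates (cm), nondecreasing from base to rim.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise GeometryError("profile x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise GeometryError("profile needs at least 2 points")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise GeometryError("profile coordinates must be finite")
        if np.any(x < -1e-12):
            raise GeometryError("profile x (radial) coordinates must be >= 0")
        object.__setattr__(self, "x", np.maximum(x, 0.0))
        object.__setattr__(self, "y", y)

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def height(self) -> float:
        return float(self.y.max() - self.y.min())

    def as_array(self) -> np.ndarray:
        """Return the points as an ``(n, 2)`` array."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class Outline:
    """Closed full cross-section contour, mirror-symmetric about ``x = 0``.

    The contour is traversed counterclockwise (y-up) and explicitly
    closed: the last point repeats the first.
    """

    x: np.ndarray
    y: np.ndarray
    closed: bool = field(default=True)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.size != y.size or x.size < 4:
            raise GeometryError("outline needs >= 4 points (incl. closure)")
        if abs(x[0] - x[-1]) > 1e-9 or abs(y[0] - y[-1]) > 1e-9:
            raise GeometryError("outline must be explicitly closed (first == last point)")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_points(self) -> int:
        return self.x.size

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def area(self) -> float:
        """Signed shoelace area (positive for counterclockwise traversal)."""
        x, y = self.x, self.y
        return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-centimetre conversion from a reference object of known size.

    Per-axis factors are retained because digitised video pixels need not
    be square; both reduce to a single scalar factor when equal.
    """

    px_per_cm_x: float
    px_per_cm_y: float
    reference_height_cm: float | None = None
    reference_width_cm: float | None = None

    def __post_init__(self) -> None:
        if self.px_per_cm_x <= 0 or self.px_per_cm_y <= 0:
            raise CalibrationError("calibration factors must be positive")

    @classmethod
    def from_reference(
        cls,
        height_px: float,
        width_px: float,
        height_cm: float = 36.0,
        width_cm: float = 42.0,
    ) -> "Calibration":
        """Build a calibration from the digitised dimensions of a reference
        object (defaults: a 36 cm high by 42 cm wide inverted-T target)."""
        if height_px <= 0 or width_px <= 0 or height_cm <= 0 or width_cm <= 0:
            raise CalibrationError("reference dimensions must be positive")
        return cls(
            px_per_cm_x=width_px / width_cm,
            px_per_cm_y=height_px / height_cm,
            reference_height_cm=height_cm,
            reference_width_cm=width_cm,
        )


def calibrate(points_px: np.ndarray, cal: Calibration) -> Profile:
    """Convert digitised pixel coordinates to a centimetre Profile.

    ``x_cm = x_px / px_per_cm_x`` and ``y_cm = y_px / px_per_cm_y``; point
    ordering is preserved.
    """
    pts = np.asarray(points_px, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise GeometryError("points_px must be a nonempty (n, 2) array")
    return Profile(x=pts[:, 0] / cal.px_per_cm_x, y=pts[:, 1] / cal.px_per_cm_y)


def resample_profile(p: Profile, n_points: int = 256) -> Profile:
    """Resample a profile to ``n_points`` at regular height intervals.

    Heights are equally spaced from ``min(y)`` to ``max(y)``; radial
    coordinates are obtained by linear interpolation.  Endpoints are
    preserved exactly.  Profiles whose height sequence cannot be made
    strictly increasing by a stable sort (re-entrant walls) are rejected.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    y = p.y
    x = p.x
    if not np.all(np.diff(y) > 0):
        order = np.argsort(y, kind="stable")
        y, x = y[order], x[order]
        dup = np.diff(y) <= 0
        if np.any(dup):
            # tolerate exact duplicates only when x agrees there
            idx = np.nonzero(dup)[0]
            if np.any(np.abs(x[idx] - x[idx + 1]) > 1e-9):
                raise GeometryError(
                    "re-entrant profile: duplicate heights with different radii"
                )
            keep = np.concatenate([[True], np.diff(y) > 0])
            y, x = y[keep], x[keep]
    if y[-1] - y[0] <= 0:
        raise GeometryError("degenerate profile: zero height range")
    yi = np.linspace(y[0], y[-1], n_points)
    xi = np.interp(yi, y, x)
    xi[0], xi[-1] = x[0], x[-1]
    return Profile(x=xi, y=yi)


def smooth_profile(p: Profile, cutoff: float = 0.15, order: int = 2) -> Profile:
    """Low-pass filter the radial coordinate of a uniformly resampled profile.

    A zero-phase Butterworth filter (forward-backward ``filtfilt``) is
    applied to the ``x`` sequence; heights are untouched.  ``cutoff`` is a
    fraction of the spatial Nyquist frequency of the height sampling.
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie strictly between 0 and 1 (fraction of Nyquist)")
    dy = np.diff(p.y)
    if dy.size < 7:
        raise GeometryError("profile too short to smooth")
    if not np.allclose(dy, dy[0], rtol=1e-6, atol=1e-9 * max(1.0, abs(float(p.height)))):
        raise GeometryError("smooth_profile requires a uniformly resampled profile")
    b, a = signal.butter(order, cutoff)
    xs = signal.filtfilt(b, a, p.x)
    return Profile(x=np.maximum(xs, 0.0), y=p.y.copy())


def mirror_to_outline(p: Profile, axis_tol: float = 1e-9) -> Outline:
    """Close a right-half profile into a full outline by mirroring.

    The contour starts on the rotation axis at the base and is traversed
    counterclockwise (y-up): up the right edge from base to rim, straight
    chord across the rim to the mirrored rim point, down the mirrored left
    edge, and a straight chord across the base back to the start.  On-axis
    points are not duplicated; the closure point is appended.
    """
    x, y = p.x, p.y
    pts: list[tuple[float, float]] = [(0.0, float(y[0]))]
    for xi, yi in zip(x, y):
        if xi > axis_tol:
            pts.append((float(xi), float(yi)))
    # rim chord: mirrored rim point reached through the axis crossing
    if x[-1] > axis_tol:
        pts.append((0.0, float(y[-1])))
    else:
        # profile already closes on the axis at the rim
        pts.append((0.0, float(y[-1])))
    for xi, yi in zip(x[::-1], y[::-1]):
        if xi > axis_tol:
            pts.append((float(-xi), float(yi)))
    pts.append((0.0, float(y[0])))
    arr = np.asarray(pts, dtype=float)
    # drop consecutive duplicates introduced by on-axis endpoints
    keep = np.concatenate(
        [[True], np.any(np.abs(np.diff(arr, axis=0)) > axis_tol, axis=1)]
    )
    arr = arr[keep]
    if not (abs(arr[0, 0] - arr[-1, 0]) <= axis_tol and abs(arr[0, 1] - arr[-1, 1]) <= axis_tol):
        arr = np.vstack([arr, arr[:1]])
    return Outline(x=arr[:, 0], y=arr[:, 1])


def profile_pipeline(
    points: np.ndarray,
    cal: Calibration | None = None,
    n_points: int = 256,
    cutoff: float | None = 0.15,
) -> Outline:
    """Run calibrate -> resample -> smooth -> mirror in one call.

    ``cal=None`` treats the input as already in centimetres; ``cutoff=None``
    skips smoothing.
    """
    if cal is not None:
        prof = calibrate(points, cal)
    else:
        pts = np.asarray(points, dtype=float)
        prof = Profile(x=pts[:, 0], y=pts[:, 1])
    prof = resample_profile(prof, n_points=n_points)
    if cutoff is not None:
        prof = smooth_profile(prof, cutoff=cutoff)
    return mirror_to_outline(prof)
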