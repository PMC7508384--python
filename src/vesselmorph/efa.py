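"""Elliptical Fourier analysis of closed outlines.

A closed contour ``(x(t), y(t))``, parametrised by cumulative arc length
``t`` over one traversal of perimeter ``T``, is decomposed into per-harmonic
quadruples

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

The coefficients are computed with the classic closed-form sums for a
piecewise-linear contour (the chain-code formulation generalised to real
increments), so they are the *exact* Fourier integrals of the polygon's
arc-length parametrisation.  Size is removed, when requested, by dividing
every harmonic coefficient by the semi-major axis length of the
first-harmonic ellipse and zeroing the bias terms, which leaves pure,
scale-invariant shape descriptors.

No rotation or start-point normalisation is applied: all vessel outlines
share one coordinate frame (rotation axis at ``x = 0``, base at the start
point), so orientation itself is informative and only size is corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .outline import GeometryError, Outline

__all__ = [
    "EFACoefficients",
    "efa_coefficients",
    "normalize_size",
    "reconstruct",
    "first_harmonic_semi_axes",
    "EllipticalFourierAnalysis",
    "coefficient_names",
]


@dataclass(frozen=True)
class EFACoefficients:
    """Elliptical Fourier coefficients of one closed outline.

    Attributes
    ----------
    harmonics : ndarray of shape (n_harmonics, 4)
        Rows ``(a_n, b_n, c_n, d_n)`` for n = 1..N.
    a0, c0 : float
        Bias (centroid) terms of x(t) and y(t).
    normalized : bool
        True once size has been removed (first-harmonic semi-major axis
        scaled to 1, bias terms zeroed).
    """

    harmonics: np.ndarray
    a0: float
    c0: float
    normalized: bool = False

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be an (N, 4) array with N >= 1")
        object.__setattr__(self, "harmonics", h)

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    def flatten(self) -> np.ndarray:
        """Flattened coefficient vector, ordering (a1, b1, c1, d1, a2, ...)."""
        return self.harmonics.ravel().copy()

    @classmethod
    def from_flat(
        cls, vec: np.ndarray, a0: float = 0.0, c0: float = 0.0, normalized: bool = True
    ) -> "EFACoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 4 != 0:
            raise ValueError("flat coefficient vector length must be a multiple of 4")
        return cls(harmonics=vec.reshape(-1, 4), a0=a0, c0=c0, normalized=normalized)


def coefficient_names(n_harmonics: int) -> list[str]:
    """Column names a1, b1, c1, d1, a2, ... for flattened coefficients."""
    return [f"{L}{n}" for n in range(1, n_harmonics + 1) for L in "abcd"]


def efa_coefficients(
    o: Outline, n_harmonics: int = 20, param: str = "arc_length"
) -> EFACoefficients:
    """Elliptical Fourier coefficients of a closed outline.

    By default the contour is parametrised by cumulative arc length and the
    exact piecewise-linear Fourier integrals are evaluated, so the result is
    deterministic given the outline's documented start point and traversal
    direction.  ``param='index'`` instead spaces the sample points uniformly
    in the parameter (useful when the vertices are known to be uniform in
    an analytic parameter, e.g. an ellipse sampled at its elliptic angle).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if param not in ("arc_length", "index"):
        raise ValueError("param must be 'arc_length' or 'index'")
    pts = o.as_array()
    d = np.diff(pts, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    nz = seg > 0
    d, seg = d[nz], seg[nz]
    if param == "index":
        seg = np.ones_like(seg)
    if d.shape[0] < 3:
        raise GeometryError("outline is degenerate: fewer than 3 distinct points")
    T = seg.sum()
    if T <= 0:
        raise GeometryError("outline has zero perimeter")
    t = np.concatenate([[0.0], np.cumsum(seg)])  # knots, t[-1] = T

    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    w = 2.0 * np.pi * n / T
    cos_t = np.cos(w * t[None, :])
    sin_t = np.sin(w * t[None, :])
    dcos = cos_t[:, 1:] - cos_t[:, :-1]
    dsin = sin_t[:, 1:] - sin_t[:, :-1]
    const = T / (2.0 * np.pi**2 * n**2).astype(float)

    dx_dt = d[:, 0] / seg
    dy_dt = d[:, 1] / seg
    a = const[:, 0] * (dx_dt[None, :] * dcos).sum(axis=1)
    b = const[:, 0] * (dx_dt[None, :] * dsin).sum(axis=1)
    c = const[:, 0] * (dy_dt[None, :] * dcos).sum(axis=1)
    dd = const[:, 0] * (dy_dt[None, :] * dsin).sum(axis=1)

    # bias terms: exact mean of the piecewise-linear x(t), y(t)
    xk = np.concatenate([[pts[0, 0]], pts[0, 0] + np.cumsum(d[:, 0])])
    yk = np.concatenate([[pts[0, 1]], pts[0, 1] + np.cumsum(d[:, 1])])
    a0 = float(np.sum(seg * (xk[:-1] + xk[1:]) / 2.0) / T)
    c0 = float(np.sum(seg * (yk[:-1] + yk[1:]) / 2.0) / T)

    return EFACoefficients(
        harmonics=np.column_stack([a, b, c, dd]), a0=a0, c0=c0, normalized=False
    )


def first_harmonic_semi_axes(c: EFACoefficients) -> tuple[float, float]:
    """Semi-major and semi-minor axis lengths of the first-harmonic ellipse.

    These are the singular values of the 2x2 matrix ``[[a1, b1], [c1, d1]]``.
    """
    m = c.harmonics[0].reshape(2, 2)
    s = np.linalg.svd(m, compute_uv=False)
    return float(s[0]), float(s[1])


def normalize_size(c: EFACoefficients, method: str = "semi_major") -> EFACoefficients:
    """Remove size by scaling to the first harmonic.

    ``method='semi_major'`` divides all harmonic coefficients by the
    semi-major axis length of the first-harmonic ellipse (default);
    ``method='a1'`` divides by ``|a1|``.  Bias terms are zeroed, making the
    descriptors invariant to both scale and translation.
    """
    if method == "semi_major":
        e1, _ = first_harmonic_semi_axes(c)
    elif method == "a1":
        e1 = abs(float(c.harmonics[0, 0]))
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    if e1 <= 0 or not np.isfinite(e1):
        raise GeometryError("degenerate first harmonic: cannot normalize size")
    return replace(c, harmonics=c.harmonics / e1, a0=0.0, c0=0.0, normalized=True)


def reconstruct(c: EFACoefficients, n_points: int = 256) -> Outline:
    """Evaluate the truncated Fourier series as a closed outline.

    Points are placed at ``n_points`` uniformly spaced parameter values over
    one period; the closure point is appended explicitly.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, c.n_harmonics + 1)[:, None]
    ang = 2.0 * np.pi * n * t[None, :]
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    h = c.harmonics
    x = c.a0 + h[:, 0] @ cos_a + h[:, 1] @ sin_a
    y = c.c0 + h[:, 2] @ cos_a + h[:, 3] @ sin_a
    x = np.concatenate([x, x[:1]])
    y = np.concatenate([y, y[:1]])
    return Outline(x=x, y=y)


def harmonic_power(c: EFACoefficients) -> np.ndarray:
    """Per-harmonic power ``(a^2 + b^2 + c^2 + d^2) / 2``."""
    return (c.harmonics**2).sum(axis=1) / 2.0


class EllipticalFourierAnalysis(TransformerMixin, BaseEstimator):
    """Transform closed outlines into (optionally size-normalized)
    elliptical Fourier coefficient vectors.

    Parameters
    ----------
    n_harmonics : int, default 20
        Harmonics retained; 20 captures > 99.9% of harmonic power on
        wheel-thrown vessel outlines.
    normalize : bool, default True
        Divide by the first-harmonic semi-major axis and drop bias terms,
        yielding scale- and translation-invariant shape descriptors.
    norm_method : {'semi_major', 'a1'}, default 'semi_major'
        Size normalisation variant.

    The transformer is stateless: ``fit`` only validates parameters, and
    ``transform`` maps a sequence of :class:`Outline` objects (or closed
    ``(n, 2)`` point arrays) to a ``(n_outlines, 4 * n_harmonics)`` matrix
    with the fixed column ordering ``a1, b1, c1, d1, a2, ...``.
    """

    def __init__(self, n_harmonics: int = 20, normalize: bool = True,
                 norm_method: str = "semi_major"):
        self.n_harmonics = n_harmonics
        self.normalize = normalize
        self.norm_method = norm_method

    def _validate(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.norm_method not in ("semi_major", "a1"):
            raise ValueError("norm_method must be 'semi_major' or 'a1'")

    def fit(self, X, y=None):  # noqa: D102 - sklearn signature
        self._validate()
        self.n_features_out_ = 4 * self.n_harmonics
        return self

    def transform_one(self, outline) -> EFACoefficients:
        """Coefficients of a single outline."""
        self._validate()
        if not isinstance(outline, Outline):
            arr = np.asarray(outline, dtype=float)
            outline = Outline(x=arr[:, 0], y=arr[:, 1])
        c = efa_coefficients(outline, n_harmonics=self.n_harmonics)
        if self.normalize:
            c = normalize_size(c, method=self.norm_method)
        return c

    def transform(self, X) -> np.ndarray:
        return np.vstack([self.transform_one(o).flatten() for o in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(coefficient_names(self.n_harmonics), dtype=object)
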