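"""Registration methods: CURT, identity alignment, and the truth oracle.

CURT ("Completely Useless Registration Tool") sorts the pixels of each image
in order of increasing intensity and maps each fixed-image pixel to the
moving-image pixel at the same index in the sort order.  The pairing is the
permutation that minimizes any monotone function of paired intensity
differences (a consequence of the rearrangement inequality), so it maximizes
image similarity -- while establishing no meaningful spatial correspondence
whatsoever.  It is the null model against which similarity-based
registration evaluation is tested.

The estimators follow the scikit-learn protocol: ``fit(fixed, moving)``
estimates the correspondence and exposes it as fitted attributes
(``displacement_field_``, and for CURT also ``permutation_``);
``transform(moving)`` resamples a moving image into the fixed grid
(the "reformatted" image).  Module-level functions provide the same
operations in functional form.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .scenes import AdmissibleTruth, _as_gray

__all__ = [
    "curt_register",
    "permutation_to_field",
    "field_to_permutation",
    "reformat_by_permutation",
    "reformat_by_field",
    "CurtRegistration",
    "IdentityRegistration",
    "OracleRegistration",
]


# ---------------------------------------------------------------------------
# functional core
# ---------------------------------------------------------------------------

def curt_register(fixed, moving) -> np.ndarray:
    """Rank-order pixel matching between two images of equal pixel count.

    Returns the permutation ``p`` such that fixed pixel ``i`` (row-major
    flat index) is matched to moving pixel ``p[i]``: the k-th smallest fixed
    intensity is paired with the k-th smallest moving intensity.  Ties are
    broken by ascending row-major index in both images (stable sort), so the
    result is deterministic; any tie rule yields the same similarity values.
    """
    fixed = np.asarray(fixed)
    moving = np.asarray(moving)
    if fixed.size != moving.size:
        raise ValueError(
            f"pixel-count mismatch: fixed has {fixed.size}, moving has {moving.size}"
        )
    order_fixed = np.argsort(fixed.ravel(), kind="stable")
    order_moving = np.argsort(moving.ravel(), kind="stable")
    p = np.empty(fixed.size, dtype=np.intp)
    p[order_fixed] = order_moving
    return p


def _check_permutation(p, n: int) -> np.ndarray:
    p = np.asarray(p)
    if p.shape != (n,):
        raise ValueError(f"permutation has shape {p.shape}, expected ({n},)")
    seen = np.zeros(n, dtype=bool)
    seen[p] = True
    if not seen.all():
        raise ValueError("not a bijection: some moving pixel indices are missing")
    return p


def permutation_to_field(p, shape: tuple[int, int]) -> np.ndarray:
    """Express a pixel permutation as a displacement field on ``shape``.

    At fixed pixel (x, y) matched to moving pixel (x', y'), the field value
    is ``(u_x, u_y) = (x' - x, y' - y)``.  Returns an (H, W, 2) float array
    with ``[..., 0] = u_x`` and ``[..., 1] = u_y``.
    """
    h, w = shape
    p = _check_permutation(p, h * w)
    y, x = np.divmod(np.arange(h * w), w)
    ym, xm = np.divmod(p, w)
    field = np.empty((h * w, 2), dtype=np.float64)
    field[:, 0] = xm - x
    field[:, 1] = ym - y
    return field.reshape(h, w, 2)


def field_to_permutation(field) -> np.ndarray:
    """Read an integer-valued, bijective displacement field back as pairings.

    Inverse of :func:`permutation_to_field`; raises if the field has
    non-integer values or maps two pixels to the same target.
    """
    field = _check_field(field)
    h, w = field.shape[:2]
    if not np.array_equal(field, np.rint(field)):
        raise ValueError("field has non-integer displacements; no permutation exists")
    y, x = np.divmod(np.arange(h * w), w)
    xt = x + field[..., 0].ravel().astype(np.intp)
    yt = y + field[..., 1].ravel().astype(np.intp)
    if (xt < 0).any() or (xt >= w).any() or (yt < 0).any() or (yt >= h).any():
        raise ValueError("field maps pixels outside the image; no permutation exists")
    return _check_permutation(yt * w + xt, h * w)


def reformat_by_permutation(moving, p) -> np.ndarray:
    """Resample the moving image through a pixel permutation.

    Output pixel at fixed flat index ``i`` holds the moving intensity at
    ``p[i]``; the intensity multiset is conserved exactly.
    """
    moving = np.asarray(moving)
    p = _check_permutation(p, moving.size)
    return moving.ravel()[p].reshape(moving.shape)


def _check_field(field) -> np.ndarray:
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 3 or field.shape[2] != 2:
        raise ValueError(f"field must have shape (H, W, 2), got {field.shape}")
    if not np.isfinite(field).all():
        raise ValueError("field contains non-finite displacements")
    return field


def reformat_by_field(moving, field, mode: str = "clamp", return_oob_count: bool = False):
    """Resample the moving image through a displacement field.

    The output at (x, y) is the moving image sampled at
    ``(x + u_x, y + u_y)`` with nearest-neighbor rounding.  Coordinates
    falling outside the moving image are clamped to the nearest edge pixel
    (``mode="clamp"``, default) or wrapped periodically (``mode="wrap"``,
    provided for illustration only -- periodic wraparound is an artifact of
    the behavior this package exists to criticize, not a sound default).
    With ``return_oob_count=True`` also returns the number of out-of-bounds
    samples.
    """
    moving = np.asarray(moving)
    field = _check_field(field)
    h, w = moving.shape
    if field.shape[:2] != (h, w):
        raise ValueError(f"field grid {field.shape[:2]} != image grid {(h, w)}")
    yy, xx = np.mgrid[0:h, 0:w]
    xs = np.rint(xx + field[..., 0]).astype(np.int64)
    ys = np.rint(yy + field[..., 1]).astype(np.int64)
    oob = (xs < 0) | (xs >= w) | (ys < 0) | (ys >= h)
    if mode == "clamp":
        xs = np.clip(xs, 0, w - 1)
        ys = np.clip(ys, 0, h - 1)
    elif mode == "wrap":
        xs %= w
        ys %= h
    else:
        raise ValueError(f"unknown mode {mode!r}; choose 'clamp' or 'wrap'")
    out = moving[ys, xs]
    if return_oob_count:
        return out, int(oob.sum())
    return out


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _BaseRegistration(TransformerMixin, BaseEstimator):
    """Common fit/transform plumbing for registration methods."""

    def fit(self, fixed, moving):
        fixed = _as_gray(np.asarray(fixed), "fixed")
        moving = _as_gray(np.asarray(moving), "moving")
        if fixed.shape != moving.shape:
            raise ValueError(
                f"shape mismatch: fixed {fixed.shape}, moving {moving.shape}"
            )
        self.fixed_shape_ = fixed.shape
        self._fit(fixed, moving)
        return self

    def _fit(self, fixed, moving):  # pragma: no cover - abstract
        raise NotImplementedError

    def transform(self, moving):
        """Reformat a moving image into the fixed grid."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "displacement_field_")
        moving = np.asarray(moving)
        if moving.shape != self.fixed_shape_:
            raise ValueError(
                f"moving shape {moving.shape} != fitted shape {self.fixed_shape_}"
            )
        return reformat_by_field(moving, self.displacement_field_)

    def fit_transform(self, fixed, moving):
        return self.fit(fixed, moving).transform(moving)


class CurtRegistration(_BaseRegistration):
    """Rank-order pixel permutation "registration" (the CURT null model).

    Fitted attributes
    -----------------
    permutation_ : ndarray of intp, shape (n_pixels,)
        Bijection from fixed to moving row-major pixel indices.
    displacement_field_ : ndarray, shape (H, W, 2)
        The permutation expressed as per-pixel (u_x, u_y) displacements.

    ``transform`` applies the permutation directly, so intensity
    conservation is exact: if the moving image is any spatial permutation of
    the fixed image, the reformatted output reproduces the fixed image
    bit for bit (hence RRMS = 0 and EID = 0).
    """

    def _fit(self, fixed, moving):
        self.permutation_ = curt_register(fixed, moving)
        self.displacement_field_ = permutation_to_field(
            self.permutation_, fixed.shape
        )

    def transform(self, moving):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "permutation_")
        moving = np.asarray(moving)
        if moving.shape != self.fixed_shape_:
            raise ValueError(
                f"moving shape {moving.shape} != fitted shape {self.fixed_shape_}"
            )
        return reformat_by_permutation(moving, self.permutation_)


class IdentityRegistration(_BaseRegistration):
    """The do-nothing baseline: zero displacement everywhere.

    On the copy-shift-paste scene this is correct on regions A and D (where
    u = (0,0) is admissible) and wrong by exactly the shift on region B --
    yet its reformatted image looks *worse* than CURT's on every similarity
    metric, which is the point of the benchmark.
    """

    def _fit(self, fixed, moving):
        h, w = fixed.shape
        self.displacement_field_ = np.zeros((h, w, 2), dtype=np.float64)


class OracleRegistration(_BaseRegistration):
    """Ground-truth oracle: picks an admissible displacement at each pixel.

    Parameters
    ----------
    truth : AdmissibleTruth
        The scene's ground truth; region C (undefined correspondence) gets a
        zero displacement, which evaluation excludes anyway.
    """

    def __init__(self, truth: AdmissibleTruth | None = None):
        self.truth = truth

    def _fit(self, fixed, moving):
        if self.truth is None:
            raise ValueError("OracleRegistration requires truth=AdmissibleTruth(...)")
        if self.truth.shape != fixed.shape:
            raise ValueError(
                f"truth grid {self.truth.shape} != image grid {fixed.shape}"
            )
        self.displacement_field_ = self.truth.oracle_field()
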