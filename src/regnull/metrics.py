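"""Similarity metrics between a fixed and a reformatted image.

Three measures, computed between a fixed image and a moving image resampled
into its grid:

* **RRMS** -- root residual mean squares, ``sqrt(mean((a - b)^2))``, in
  intensity units; 0 iff the images are identical.
* **CC** -- Pearson cross-correlation of paired pixel intensities, in
  [-1, 1]; undefined (raises) when either image is constant.  Note that
  RRMS = 0 forces CC = 1 under this definition.
* **EID** -- entropy of the image difference: Shannon entropy (base 2 by
  default, i.e. bits) of the normalized histogram of ``a - b``, one bin per
  integer difference value by default; 0 iff the difference is constant.

These are the standard definitions; bin width and logarithm base are
configurable so alternate conventions can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _shannon_entropy

__all__ = [
    "ConstantImageError",
    "SimilarityTriple",
    "rrms",
    "cc",
    "eid",
    "similarity_report",
]


class ConstantImageError(ValueError):
    """Raised when a correlation is requested of a zero-variance image."""


def _pair(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rrms(a, b) -> float:
    """Root of the mean squared pixelwise intensity difference.

    Symmetric, zero iff ``a == b``, and a true metric on images (it is the
    Euclidean distance scaled by 1/sqrt(n)).
    """
    a, b = _pair(a, b)
    d = a.astype(np.float64) - b.astype(np.float64)
    return float(np.sqrt(np.mean(d * d)))


def cc(a, b) -> float:
    """Pearson correlation of paired pixel intensities.

    Invariant under positive affine rescaling of either image.  Raises
    :class:`ConstantImageError` on a constant input (zero variance).
    """
    a, b = _pair(a, b)
    af = a.astype(np.float64).ravel()
    bf = b.astype(np.float64).ravel()
    da = af - af.mean()
    db = bf - bf.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise ConstantImageError("correlation undefined: constant input image")
    return float((da @ db) / np.sqrt(va * vb))


def eid(a, b, bin_width: float = 1.0, base: float = 2.0) -> float:
    """Shannon entropy of the difference-image intensity distribution.

    With the default ``bin_width=1`` on integer images this uses exactly one
    bin per integer difference value in ``[-max, +max]`` (empty bins
    contribute nothing), so it is parameter-free and exact for 8-bit data.
    Invariant to adding a constant offset to either image would *not* hold
    (the difference shifts bins) but invariance to adding the same constant
    to both does; zero iff the difference image is constant.
    """
    a, b = _pair(a, b)
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = a.astype(np.float64) - b.astype(np.float64)
    if bin_width == 1.0:
        if not (np.issubdtype(a.dtype, np.integer) and np.issubdtype(b.dtype, np.integer)):
            raise ValueError(
                "unit bin width requires integer images; set bin_width explicitly"
            )
        di = (a.astype(np.int64) - b.astype(np.int64)).ravel()
    else:
        di = np.floor(d.ravel() / bin_width).astype(np.int64)
    counts = np.bincount(di - di.min())
    return float(_shannon_entropy(counts[counts > 0], base=base))


@dataclass(frozen=True)
class SimilarityTriple:
    """The RRMS / CC / EID bundle for one fixed-vs-reformatted pair.

    Lower is better for ``rrms`` and ``eid``; higher is better for ``cc``.
    """

    rrms: float
    cc: float
    eid: float

    #: per-metric orientation: +1 means larger values are better
    DIRECTIONS = {"rrms": -1, "cc": +1, "eid": -1}

    def dominates(self, other: "SimilarityTriple") -> bool:
        """True if self is strictly better than ``other`` on all three metrics."""
        return (
            self.rrms < other.rrms
            and self.cc > other.cc
            and self.eid < other.eid
        )

    def as_dict(self) -> dict[str, float]:
        return {"rrms": self.rrms, "cc": self.cc, "eid": self.eid}


def similarity_report(fixed, reformatted, bin_width: float = 1.0,
                      base: float = 2.0) -> SimilarityTriple:
    """Compute the full similarity triple between fixed and reformatted images."""
    return SimilarityTriple(
        rrms=rrms(fixed, reformatted),
        cc=cc(fixed, reformatted),
        eid=eid(fixed, reformatted, bin_width=bin_width, base=base),
    )
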