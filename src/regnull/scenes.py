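"""Synthetic copy-shift-paste scenes with exact multi-valued ground truth.

The moving image is constructed from the fixed image by copying a rectangular
sub-region anchored at the top-left corner and pasting it ``shift`` pixels to
the right, over existing content.  This purely mechanical construction
partitions the fixed image into four regions with known admissible
displacements:

====== ============================ ==============================
label  content                      admissible displacements
====== ============================ ==============================
A      duplicated (copied, kept)    {(0, 0), (shift, 0)}
B      displaced (copied, covered)  {(shift, 0)}
C      overwritten, never copied    {}  (correspondence undefined)
D      unmoved                      {(0, 0)}
====== ============================ ==============================

A displacement ``u = (u_x, u_y)`` at fixed pixel ``(x, y)`` (x = column,
y = row, both 0-based) means the corresponding moving-image location is
``(x + u_x, y + u_y)``.  For every pixel with a non-empty admissible set and
every admissible ``u``, intensity constancy holds exactly:
``moving[y + u_y, x + u_x] == fixed[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneSpec",
    "AdmissibleTruth",
    "render_scene",
    "copy_shift_paste",
    "add_noise",
    "REGION_LABELS",
    "REGION_CODES",
]

#: Region-label encoding used wherever labels are stored as integers
#: (e.g. in the serialized label map): A=1, B=2, C=3, D=4.
REGION_CODES = {"A": 1, "B": 2, "C": 3, "D": 4}
REGION_LABELS = {v: k for k, v in REGION_CODES.items()}

TEXTURES = ("smooth-noise", "unique-ramp", "flat")


def _as_gray(image, name: str = "image") -> np.ndarray:
    """Validate a 2D integer grayscale image and return it as an ndarray."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{name} must have integer intensities, got {arr.dtype}")
    return arr


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one copy-shift-paste scene.

    Defaults reproduce the canonical construction: a 156x196-pixel top-left
    region shifted right by 50 pixels on a 206x256 (width x height) canvas,
    so that the pasted copy lands flush in the top-right corner.

    Parameters
    ----------
    width, height : int
        Canvas size in pixels.
    region_width, region_height : int
        Size of the copied rectangle, anchored at the top-left corner.
    shift : int
        Horizontal paste offset in pixels; must be positive and satisfy
        ``region_width + shift <= width``.
    texture : str
        Background texture: ``"smooth-noise"`` (band-limited random texture,
        default), ``"unique-ramp"`` (all pixel intensities distinct; needs an
        intensity range of at least one value per pixel) or ``"flat"``.
    ball_radius : int
        Radius of the bright disk ("ball"); 0 suppresses it.
    ball_center : (int, int) or None
        Disk center as (x, y); ``None`` places it at mid-canvas, inside the
        copied region for the default geometry.
    max_intensity : int
        Upper bound of the intensity range.  255 gives 8-bit images; the
        unique-ramp texture raises it automatically if the canvas has more
        pixels than intensity levels.
    seed : int
        RNG seed; generation is a pure function of (spec, seed).
    """

    width: int = 206
    height: int = 256
    region_width: int = 156
    region_height: int = 196
    shift: int = 50
    texture: str = "smooth-noise"
    ball_radius: int = 42
    ball_center: tuple[int, int] | None = None
    max_intensity: int = 255
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height) < 1:
            raise ValueError("canvas dimensions must be positive")
        if min(self.region_width, self.region_height) < 1:
            raise ValueError("copied-region dimensions must be positive")
        if self.shift <= 0:
            raise ValueError("shift must be > 0 (a zero shift copies in place)")
        if self.region_width + self.shift > self.width:
            raise ValueError(
                f"region_width + shift = {self.region_width + self.shift} "
                f"exceeds image width {self.width}"
            )
        if self.region_height > self.height:
            raise ValueError("region_height exceeds image height")
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}; choose from {TEXTURES}")
        if self.max_intensity < 1:
            raise ValueError("max_intensity must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["ball_center"] is not None:
            d["ball_center"] = list(d["ball_center"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown SceneSpec keys: {sorted(unknown)}")
        if d.get("ball_center") is not None:
            d["ball_center"] = tuple(d["ball_center"])
        return cls(**d)


@dataclass
class AdmissibleTruth:
    """Per-pixel ground truth as a set of admissible displacements.

    The set may be multi-valued (region A: duplicated content has two equally
    correct mappings), single-valued (B, D), or empty (region C, where the
    original content was pasted over and correspondence is undefined).

    Attributes
    ----------
    labels : ndarray of uint8, shape (H, W)
        Region code per pixel (A=1, B=2, C=3, D=4).
    shift : int
        The horizontal paste offset; determines the admissible sets.
    """

    labels: np.ndarray
    shift: int
    spec: SceneSpec | None = field(default=None, repr=False)

    #: label -> tuple of admissible (u_x, u_y) displacements
    def admissible(self, label: str) -> tuple[tuple[int, int], ...]:
        s = self.shift
        table = {
            "A": ((0, 0), (s, 0)),
            "B": ((s, 0),),
            "C": (),
            "D": ((0, 0),),
        }
        return table[label]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_mask(self, label: str) -> np.ndarray:
        return self.labels == REGION_CODES[label]

    def region_areas(self) -> dict[str, int]:
        return {lab: int(self.region_mask(lab).sum()) for lab in "ABCD"}

    def admissible_sets(self) -> dict[str, tuple[tuple[int, int], ...]]:
        return {lab: self.admissible(lab) for lab in "ABCD"}

    def oracle_field(self) -> np.ndarray:
        """A displacement field that is admissible at every defined pixel.

        Picks the first element of each admissible set ((0,0) for A and D,
        (shift,0) for B); region C, where no displacement is correct, is
        filled with (0,0) -- it is excluded from any error aggregate anyway.
        """
        h, w = self.labels.shape
        u = np.zeros((h, w, 2), dtype=np.float64)
        u[self.region_mask("B"), 0] = self.shift
        return u


def render_scene(spec: SceneSpec) -> np.ndarray:
    """Render the fixed image: a bright disk on a textured background.

    Deterministic given ``spec`` (including its seed).  The ``unique-ramp``
    texture assigns every pixel a distinct intensity (widening the integer
    range beyond 8 bits if the canvas demands it), with the largest values
    concentrated in the disk so the ball stays the brightest object.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    yy, xx = np.mgrid[0:h, 0:w]
    if spec.ball_center is None:
        cx, cy = w // 2, int(h * 0.38)
    else:
        cx, cy = spec.ball_center
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.ball_radius**2

    if spec.texture == "unique-ramp":
        n = h * w
        max_i = max(spec.max_intensity, n - 1)
        values = np.arange(n, dtype=np.int64 if max_i > 255 else np.uint8)
        img = np.empty(n, dtype=values.dtype)
        flat_disk = disk.ravel()
        n_disk = int(flat_disk.sum())
        # brightest values inside the disk, the rest shuffled over background
        img[flat_disk] = rng.permutation(values[n - n_disk:])
        img[~flat_disk] = rng.permutation(values[: n - n_disk])
        return img.reshape(h, w)

    max_i = spec.max_intensity
    if spec.texture == "flat":
        base = np.full((h, w), 0.35 * max_i)
    else:  # smooth-noise: band-limited random texture
        base = gaussian_filter(rng.uniform(0.0, 1.0, size=(h, w)), sigma=3.0)
        lo, hi = base.min(), base.max()
        base = 0.08 * max_i + (0.55 - 0.08) * max_i * (base - lo) / (hi - lo)

    if spec.ball_radius > 0:
        # bright ball with a mild radial shading so it is not one flat level
        r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        ball = (0.92 - 0.18 * r / max(spec.ball_radius, 1)) * max_i
        base = np.where(disk, ball, base)

    img = np.clip(np.rint(base), 0, max_i)
    return img.astype(np.uint8 if max_i <= 255 else np.int64)


def copy_shift_paste(fixed, spec: SceneSpec) -> tuple[np.ndarray, AdmissibleTruth]:
    """Build the moving image and its ground truth from a fixed image.

    The top-left ``region_width x region_height`` rectangle of ``fixed`` is
    copied and pasted ``shift`` pixels to the right, overwriting existing
    content.  Returns the moving image and the :class:`AdmissibleTruth`
    labelling every pixel A/B/C/D with its admissible displacement set.

    Region geometry follows from the mechanics: a pixel that was copied and
    not pasted over keeps two correct mappings (A); copied and pasted over,
    only the shifted one (B); pasted over but never copied, none (C);
    untouched pixels map to themselves (D).
    """
    fixed = _as_gray(fixed, "fixed")
    h, w = fixed.shape
    if (w, h) != (spec.width, spec.height):
        raise ValueError(
            f"fixed image is {w}x{h} (WxH) but spec declares "
            f"{spec.width}x{spec.height}"
        )
    rw, rh, s = spec.region_width, spec.region_height, spec.shift

    moving = fixed.copy()
    moving[0:rh, s:s + rw] = fixed[0:rh, 0:rw]

    xx = np.arange(w)[None, :]
    yy = np.arange(h)[:, None]
    copied = (xx < rw) & (yy < rh)
    pasted_over = (xx >= s) & (xx < s + rw) & (yy < rh)

    labels = np.full((h, w), REGION_CODES["D"], dtype=np.uint8)
    labels[copied & ~pasted_over] = REGION_CODES["A"]
    labels[copied & pasted_over] = REGION_CODES["B"]
    labels[~copied & pasted_over] = REGION_CODES["C"]

    return moving, AdmissibleTruth(labels=labels, shift=s, spec=spec)


def add_noise(image, sigma: float, seed: int = 0, max_intensity: int | None = None) -> np.ndarray:
    """Add rounded Gaussian intensity noise, clipped to the valid range.

    Off by default in the experiment pipeline: the copy-shift-paste
    construction is exact, and the permutation-null identities (CURT
    reproducing the fixed image bit-exactly from a permuted copy) hold only
    under exact intensity conservation.  ``sigma=0`` returns the input
    unchanged; otherwise the result is deterministic given ``seed``.
    """
    image = _as_gray(image)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    if max_intensity is None:
        max_intensity = 255 if image.dtype == np.uint8 else int(image.max())
    rng = np.random.default_rng(seed)
    noisy = image.astype(np.float64) + rng.normal(0.0, sigma, size=image.shape)
    return np.clip(np.rint(noisy), 0, max_intensity).astype(image.dtype)
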