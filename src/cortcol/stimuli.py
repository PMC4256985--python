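"""Synthetic pictogram stimuli and presentation schedules.

Two categories of binary line drawings on a 100 x 100 grid of intensities
in [0, 1]:

* category ``A`` -- four pictographic faces sharing an identical head
  outline and eyes, differing only in the shape of the mouth;
* category ``B`` -- four squares sharing an identical outline, each
  enclosing a single interior bar (two horizontal, two vertical) at a
  position unique to the variant.

Each category therefore has a non-trivial intra-category intersection
(the shared structure an *overall* category cell can latch onto) while
every variant carries disjoint or near-disjoint private evidence (what a
*subcategory* cell encodes).  During training, zero-mean Gaussian noise
(default sigma = 0.05) is added independently per presentation and the
result is clipped back into [0, 1].

Geometry is parametric; the defaults put the foreground pixel count of
every variant inside the 1200-1600 band so that the squared input energy
of a clean stimulus is roughly 1400, twice the default midpoint of the
layer-3 logistic transfer function (a stimulus at half energy then sits
at the logistic midpoint).
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "Image",
    "StimulusSet",
    "StimulusStream",
    "FaceGeometry",
    "SquareGeometry",
    "render_face_variant",
    "render_square_variant",
    "face_set",
    "square_set",
    "add_noise",
    "build_stream",
    "write_image",
    "read_image",
]

DEFAULT_SIZE = (100, 100)

CategoryLabel = Literal["A", "B"]
Schedule = Literal["blocked", "random"]


@dataclasses.dataclass(frozen=True)
class Image:
    """A grayscale stimulus: ``pixels`` of shape (height, width) in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("image must be non-empty")
        if np.nanmin(px) < 0.0 or np.nanmax(px) > 1.0 or not np.all(np.isfinite(px)):
            raise ValueError("image intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def flatten(self) -> np.ndarray:
        """Row-major length-N activity vector (N = height * width)."""
        return self.pixels.reshape(-1)


@dataclasses.dataclass(frozen=True)
class StimulusSet:
    """The four variants of one category, indexed by variation label 1..4."""

    category_label: CategoryLabel
    images: tuple[Image, ...]

    def __post_init__(self) -> None:
        if len(self.images) != 4:
            raise ValueError("a category holds exactly 4 variants")
        shapes = {im.pixels.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError("all variants must share one image size")

    def variant(self, variant_id: int) -> Image:
        _check_variant(variant_id)
        return self.images[variant_id - 1]

    def intersection(self) -> np.ndarray:
        """Pixelwise intersection mask over the four variants."""
        stack = np.stack([im.pixels > 0 for im in self.images])
        return np.logical_and.reduce(stack)

    def union(self) -> np.ndarray:
        stack = np.stack([im.pixels > 0 for im in self.images])
        return np.logical_or.reduce(stack)


def _check_variant(variant_id: int) -> None:
    if variant_id not in (1, 2, 3, 4):
        raise ValueError(f"variant_id must be in 1..4, got {variant_id!r}")


def _check_size(size: tuple[int, int]) -> tuple[int, int]:
    h, w = int(size[0]), int(size[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"image size must be positive, got {size!r}")
    return h, w


# ---------------------------------------------------------------------------
# geometry


@dataclasses.dataclass(frozen=True)
class FaceGeometry:
    """Parametric face pictogram: circular head outline, filled eyes, mouth.

    Distances are in pixels relative to the image size; defaults target a
    100 x 100 canvas.
    """

    head_radius: float = 42.0
    head_stroke: float = 3.5
    eye_dy: float = -12.0
    eye_dx: float = 14.0
    eye_radius: float = 6.0
    # mouth bounding box (rows, cols), identical for all variants
    mouth_rows: tuple[int, int] = (56, 84)
    mouth_cols: tuple[int, int] = (28, 72)


@dataclasses.dataclass(frozen=True)
class SquareGeometry:
    """Parametric square pictogram: outline plus one interior bar."""

    margin: int = 10  # outline runs from margin to size-margin-1
    stroke: int = 4
    bar_thickness: int = 6
    bar_length: int = 40


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    return rows, cols


def _disk(h: int, w: int, cr: float, cc: float, radius: float) -> np.ndarray:
    rows, cols = _grid(h, w)
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2


def _annulus(h: int, w: int, cr: float, cc: float, r_in: float, r_out: float) -> np.ndarray:
    rows, cols = _grid(h, w)
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    return (d2 >= r_in**2) & (d2 < r_out**2)


def _face_base(h: int, w: int, geo: FaceGeometry) -> np.ndarray:
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    head = _annulus(h, w, cr, cc, geo.head_radius - geo.head_stroke, geo.head_radius)
    left = _disk(h, w, cr + geo.eye_dy, cc - geo.eye_dx, geo.eye_radius)
    right = _disk(h, w, cr + geo.eye_dy, cc + geo.eye_dx, geo.eye_radius)
    return head | left | right


def _face_mouth(h: int, w: int, variant_id: int, geo: FaceGeometry) -> np.ndarray:
    cc = (w - 1) / 2.0
    rows, cols = _grid(h, w)
    # The four shapes are laid out to keep a substantial set of pixels
    # unique to each variant: the variant-specific evidence is what the
    # residual feedback amplifies when a subcategory is recruited.
    if variant_id == 1:  # neutral: straight horizontal stroke
        return (rows >= 57) & (rows <= 62) & (cols >= 34) & (cols <= 65)
    if variant_id == 2:  # smile: downward arc
        arc = _annulus(h, w, 62.0, cc, 17.0, 22.0)
        return arc & (rows >= 66)
    if variant_id == 3:  # frown: upward arc
        arc = _annulus(h, w, 86.0, cc, 17.0, 24.0)
        return arc & (rows <= 70)
    # variant 4 -- open mouth: filled ellipse
    return ((rows - 74.0) / 5.5) ** 2 + ((cols - cc) / 13.0) ** 2 <= 1.0


def render_face_variant(
    variant_id: int,
    size: tuple[int, int] = DEFAULT_SIZE,
    geometry: FaceGeometry | None = None,
) -> Image:
    """Render one of the four face pictograms (category A).

    Variants share the head outline and eyes bit-for-bit; only the mouth
    stroke -- confined to ``geometry.mouth_rows`` x ``geometry.mouth_cols``
    -- differs.
    """
    _check_variant(variant_id)
    h, w = _check_size(size)
    geo = geometry or FaceGeometry()
    mask = _face_base(h, w, geo) | _face_mouth(h, w, variant_id, geo)
    return Image(mask.astype(float))


def _square_bars(h: int, w: int, geo: SquareGeometry) -> list[tuple[slice, slice]]:
    # Four pairwise-disjoint bar placements inside the outline: two
    # horizontal (variants 1, 2) and two vertical (variants 3, 4).  The
    # placements also avoid the face mouth and eye boxes so that neither
    # category's variant-specific evidence overlaps the other's.
    t, ln = geo.bar_thickness, geo.bar_length
    return [
        (slice(20, 20 + t), slice(18, 18 + ln)),  # horizontal, upper left
        (slice(50, 50 + t), slice(30, 30 + ln)),  # horizontal, center
        (slice(18, 18 + ln), slice(74, 74 + t)),  # vertical, right
        (slice(30, 30 + ln), slice(20, 20 + t)),  # vertical, left
    ]


def render_square_variant(
    variant_id: int,
    size: tuple[int, int] = DEFAULT_SIZE,
    geometry: SquareGeometry | None = None,
) -> Image:
    """Render one of the four square-with-bar pictograms (category B)."""
    _check_variant(variant_id)
    h, w = _check_size(size)
    geo = geometry or SquareGeometry()
    m, s = geo.margin, geo.stroke
    mask = np.zeros((h, w), dtype=bool)
    mask[m : h - m, m : w - m] = True
    mask[m + s : h - m - s, m + s : w - m - s] = False
    rs, cs = _square_bars(h, w, geo)[variant_id - 1]
    mask[rs, cs] = True
    return Image(mask.astype(float))


def face_set(size: tuple[int, int] = DEFAULT_SIZE, geometry: FaceGeometry | None = None) -> StimulusSet:
    return StimulusSet("A", tuple(render_face_variant(i, size, geometry) for i in (1, 2, 3, 4)))


def square_set(size: tuple[int, int] = DEFAULT_SIZE, geometry: SquareGeometry | None = None) -> StimulusSet:
    return StimulusSet("B", tuple(render_square_variant(i, size, geometry) for i in (1, 2, 3, 4)))


def category_set(label: CategoryLabel, size: tuple[int, int] = DEFAULT_SIZE) -> StimulusSet:
    if label == "A":
        return face_set(size)
    if label == "B":
        return square_set(size)
    raise ValueError(f"unknown category label {label!r}")


# ---------------------------------------------------------------------------
# noise and streams


def add_noise(img: Image, sigma: float, rng: np.random.Generator) -> Image:
    """Add independent zero-mean Gaussian noise per pixel, clip to [0, 1]."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return img
    noisy = img.pixels + rng.normal(0.0, sigma, size=img.pixels.shape)
    return Image(np.clip(noisy, 0.0, 1.0))


@dataclasses.dataclass(frozen=True)
class Presentation:
    image: Image
    category_label: CategoryLabel
    variation_label: int


@dataclasses.dataclass(frozen=True)
class StimulusStream:
    """A reproducible ordered schedule of noisy stimulus presentations.

    The clean variants, the presentation order and the seed are stored;
    noise is drawn afresh per presentation when iterating, so two
    iterations of the same stream are bit-identical while distinct seeds
    give distinct noise and (for the random schedule) distinct orderings.
    """

    sets: tuple[StimulusSet, ...]
    order: np.ndarray  # (n_steps, 2) int array of (set index, variant 1..4)
    schedule: Schedule
    block_size: int
    noise_sigma: float
    seed: int

    @property
    def n_steps(self) -> int:
        return len(self.order)

    def labels(self) -> list[tuple[CategoryLabel, int]]:
        return [(self.sets[si].category_label, int(vi)) for si, vi in self.order]

    def presentations(self) -> Iterator[Presentation]:
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x5EED]))
        for si, vi in self.order:
            st = self.sets[int(si)]
            img = add_noise(st.variant(int(vi)), self.noise_sigma, rng)
            yield Presentation(img, st.category_label, int(vi))


def build_stream(
    sets: StimulusSet | Sequence[StimulusSet],
    schedule: Schedule = "random",
    block_size: int = 100,
    n_steps: int = 400,
    seed: int = 0,
    noise_sigma: float = 0.05,
) -> StimulusStream:
    """Build a presentation schedule over one or two stimulus sets.

    ``blocked`` cycles through all (set, variant) pairs in sorted order,
    emitting ``block_size`` consecutive presentations of each; ``random``
    draws the pair uniformly and independently at every step.
    """
    if isinstance(sets, StimulusSet):
        sets = (sets,)
    sets = tuple(sets)
    if not sets:
        raise ValueError("at least one stimulus set is required")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")

    # Variant-major pair order: with a single set this is the plain sorted
    # cycle; with two sets the blocked schedule alternates categories
    # block-by-block (A1, B1, A2, B2, ...), so every variant's block is
    # revisited within two category exposures.
    pairs = [(si, vi) for vi in (1, 2, 3, 4) for si in range(len(sets))]
    if schedule == "blocked":
        order = [pairs[(t // block_size) % len(pairs)] for t in range(n_steps)]
    elif schedule == "random":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0BDE8]))
        order = [pairs[i] for i in rng.integers(0, len(pairs), size=n_steps)]
    else:
        raise ValueError(f"unknown schedule {schedule!r}")
    return StimulusStream(
        sets=sets,
        order=np.asarray(order, dtype=int),
        schedule=schedule,
        block_size=block_size,
        noise_sigma=noise_sigma,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# image I/O (PNG via imageio, PGM written directly in plain-text P2 form)


def write_image(img: Image, path: str) -> None:
    """Write an image as 8-bit PNG or plain-text PGM, by file extension."""
    path = str(path)
    quantized = np.round(img.pixels * 255).astype(np.uint8)
    if path.endswith(".pgm"):
        h, w = quantized.shape
        lines = [f"P2", f"{w} {h}", "255"]
        lines += [" ".join(str(v) for v in row) for row in quantized]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        import imageio.v3 as iio

        iio.imwrite(path, quantized)


def read_image(path: str) -> Image:
    path = str(path)
    if path.endswith(".pgm"):
        with open(path) as fh:
            tokens = [t for line in fh if not line.startswith("#") for t in line.split()]
        if tokens[0] != "P2":
            raise ValueError("only plain-text (P2) PGM files are supported")
        w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
        data = np.array(tokens[4 : 4 + w * h], dtype=float).reshape(h, w)
        return Image(data / maxval)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return Image(arr / 255.0)
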