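"""Gel image stack preprocessing.

Reads grayscale blot images into an :class:`ImageStack`, subtracts a
global percentile background, registers the stack by integer-pixel
translation (cross-correlation argmax) and rescales every image to the
stack's median total intensity, so that a per-pixel rank statistic across
samples compares like with like.

Axis semantics follow the 2D gel convention: x is the isoelectric point
(pI) axis increasing left to right, y is molecular weight decreasing top
to bottom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    AlignmentError,
    DegenerateInputError,
    FormatError,
    ParameterError,
    ShapeMismatchError,
)
from .synthetic import translate_image

__all__ = [
    "GelImage",
    "ImageStack",
    "CovariateVector",
    "load_stack",
    "save_stack",
    "subtract_background",
    "subtract_background_stack",
    "align_stack",
    "normalize_stack",
    "preprocess_stack",
]


@dataclass
class GelImage:
    """One sample's gel image with nonnegative float intensities."""

    pixels: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"{self.sample_id}: expected a 2D grayscale image, "
                f"got shape {self.pixels.shape} (select a channel explicitly "
                "for RGB input)"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError(f"{self.sample_id}: non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """Ordered stack of same-shape gel images, one per sample."""

    images: list[GelImage]
    aligned: bool = False
    normalized: bool = False
    alignment_flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.images:
            raise ParameterError("empty stack")
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"mixed image shapes in stack: {sorted(shapes)}")
        ids = [im.sample_id for im in self.images]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate sample_id in stack")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[GelImage]:
        return iter(self.images)

    @property
    def sample_ids(self) -> list[str]:
        return [im.sample_id for im in self.images]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    @property
    def data(self) -> np.ndarray:
        """(n_samples, height, width) float array view of the stack."""
        return np.stack([im.pixels for im in self.images])


@dataclass
class CovariateVector:
    """Per-sample biological variable, order-matched to a stack."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "continuous"  # "continuous" | "ordinal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != len(self.values):
            raise ParameterError("sample_ids and values length mismatch")
        if self.kind not in ("continuous", "ordinal"):
            raise ParameterError(f"unknown covariate kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        value_column: str = "covariate",
        kind: str = "continuous",
    ) -> "CovariateVector":
        table = pd.read_csv(path)
        return cls(
            sample_ids=table["sample_id"].astype(str).tolist(),
            values=table[value_column].to_numpy(dtype=float),
            kind=kind,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_gray(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise FormatError(
            f"{path}: RGB/multichannel input; pass a grayscale export or "
            "select one channel explicitly"
        )
    return np.asarray(arr, dtype=float)


def load_stack(
    paths: Sequence[str | Path] | None = None,
    manifest: str | Path | None = None,
) -> ImageStack:
    """Load a stack from per-sample image files or a manifest CSV.

    The manifest needs ``sample_id`` and ``path`` columns; with bare
    ``paths`` the file stem becomes the sample id.  A single multi-page
    TIFF path is expanded into one image per page.
    """
    images: list[GelImage] = []
    if manifest is not None:
        table = pd.read_csv(manifest)
        if table["sample_id"].duplicated().any():
            raise ParameterError("duplicate sample_id in manifest")
        root = Path(manifest).parent
        for _, row in table.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = root / p
            images.append(GelImage(_read_gray(p), str(row["sample_id"])))
    elif paths is not None:
        if len(paths) == 1 and str(paths[0]).lower().endswith((".tif", ".tiff")):
            data = tifffile.imread(paths[0])
            if data.ndim == 3:
                stem = Path(paths[0]).stem
                for i, page in enumerate(data):
                    images.append(
                        GelImage(np.asarray(page, dtype=float), f"{stem}_{i + 1:02d}")
                    )
            else:
                images.append(GelImage(np.asarray(data, dtype=float), Path(paths[0]).stem))
        else:
            for p in paths:
                images.append(GelImage(_read_gray(Path(p)), Path(p).stem))
    else:
        raise ParameterError("provide either paths or a manifest")
    return ImageStack(images)


def save_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a 32-bit float multi-page TIFF."""
    tifffile.imwrite(Path(path), stack.data.astype(np.float32), photometric="minisblack")


# ---------------------------------------------------------------------------
# Background subtraction
# ---------------------------------------------------------------------------


def subtract_background(image: GelImage, q: float = 0.05) -> GelImage:
    """Subtract the image's q-quantile intensity, clipping at zero.

    A global percentile stands in for the flat membrane background; gel
    spots occupy a small area so a low quantile tracks the background
    level well, and the downstream statistic is rank-based, making the
    exact monotone choice uncritical.
    """
    if not 0.0 < q < 0.5:
        raise ParameterError("background quantile must lie in (0, 0.5)")
    if not np.any(image.pixels > 0):
        raise DegenerateInputError(f"{image.sample_id}: all-zero image")
    level = np.quantile(image.pixels, q)
    return GelImage(np.clip(image.pixels - level, 0.0, None), image.sample_id)


def subtract_background_stack(stack: ImageStack, q: float = 0.05) -> ImageStack:
    return ImageStack(
        [subtract_background(im, q) for im in stack],
        aligned=stack.aligned,
        normalized=False,
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _register_translation(
    reference: np.ndarray,
    moving: np.ndarray,
    max_displacement: int | None = 20,
) -> tuple[int, int]:
    """Integer shift (dy, dx) to apply to *moving* so it matches *reference*.

    FFT cross-correlation argmax on mean-subtracted images.  The search
    is restricted to |dy|, |dx| <= max_displacement: gel-to-gel
    misalignment is small, and an unbounded search can lock a repeated
    spot pattern (e.g. the FL charge train) onto a different spot row of
    the reference.
    """
    h, w = reference.shape
    ref_c = reference - reference.mean()
    mov_c = moving - moving.mean()
    corr = np.fft.irfft2(
        np.fft.rfft2(ref_c) * np.conj(np.fft.rfft2(mov_c)), s=(h, w)
    )
    dys = np.fft.fftfreq(h, 1.0 / h).astype(int)
    dxs = np.fft.fftfreq(w, 1.0 / w).astype(int)
    if max_displacement is not None:
        bad = (np.abs(dys)[:, None] > max_displacement) | (
            np.abs(dxs)[None, :] > max_displacement
        )
        corr = np.where(bad, -np.inf, corr)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    return int(dys[iy]), int(dxs[ix])


def align_stack(
    stack: ImageStack,
    reference: int | np.ndarray = 0,
    max_displacement: int | None = 20,
) -> tuple[ImageStack, np.ndarray]:
    """Register every image to a reference by integer-pixel translation.

    ``reference`` is a stack index or an explicit template image.
    Returns the aligned stack and the (n, 2) applied offsets (dy, dx).
    Exposed borders are filled with each image's own background estimate
    (5th percentile), not zero, to avoid spurious rank structure at the
    edges.  Flat (zero-variance) images cannot be registered: they keep a
    zero offset and their ids are recorded in ``alignment_flagged``.
    """
    if len(stack) < 2 and isinstance(reference, int):
        raise ParameterError("need >= 2 images to align")
    if isinstance(reference, int):
        if not 0 <= reference < len(stack):
            raise ParameterError(f"reference index {reference} out of range")
        ref = stack.images[reference].pixels
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != stack.shape:
            raise ShapeMismatchError("template shape differs from stack shape")
    if np.ptp(ref) == 0:
        raise AlignmentError("flat reference image")

    offsets = np.zeros((len(stack), 2), dtype=int)
    flagged: list[str] = []
    out: list[GelImage] = []
    for i, im in enumerate(stack):
        if np.ptp(im.pixels) == 0:
            flagged.append(im.sample_id)
            out.append(GelImage(im.pixels.copy(), im.sample_id))
            continue
        dy, dx = _register_translation(ref, im.pixels, max_displacement)
        offsets[i] = (dy, dx)
        if dy or dx:
            fill = float(np.quantile(im.pixels, 0.05))
            out.append(
                GelImage(translate_image(im.pixels, dy, dx, fill=fill), im.sample_id)
            )
        else:
            out.append(GelImage(im.pixels.copy(), im.sample_id))
    if flagged:
        warnings.warn(
            f"could not align flat image(s): {flagged}", RuntimeWarning, stacklevel=2
        )
    aligned = ImageStack(
        out,
        aligned=True,
        normalized=stack.normalized,
        alignment_flagged=flagged,
    )
    return aligned, offsets


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_stack(stack: ImageStack, method: str = "total_intensity") -> ImageStack:
    """Scale each image so its total intensity equals the stack median.

    Total-intensity scaling preserves relative spot proportions within an
    image (unlike quantile normalization) and makes the downstream rank
    statistic invariant to arbitrary positive per-image exposure factors.
    """
    if method != "total_intensity":
        raise ParameterError(f"unknown normalization method {method!r}")
    totals = np.array([im.pixels.sum() for im in stack])
    if np.any(totals <= 0):
        bad = [im.sample_id for im, t in zip(stack, totals) if t <= 0]
        raise DegenerateInputError(f"nonpositive total intensity for {bad}")
    target = float(np.median(totals))
    out = [
        GelImage(im.pixels * (target / t), im.sample_id)
        for im, t in zip(stack, totals)
    ]
    return ImageStack(
        out,
        aligned=stack.aligned,
        normalized=True,
        alignment_flagged=list(stack.alignment_flagged),
    )


def preprocess_stack(
    stack: ImageStack,
    background_q: float = 0.05,
    reference: int | np.ndarray = 0,
    normalization: str = "total_intensity",
) -> tuple[ImageStack, np.ndarray]:
    """Background-subtract, align and normalize a stack in one call."""
    stack = subtract_background_stack(stack, q=background_q)
    stack, offsets = align_stack(stack, reference=reference)
    stack = normalize_stack(stack, method=normalization)
    return stack, offsets
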