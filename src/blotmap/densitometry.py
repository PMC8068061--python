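"""ROI densitometry: background-corrected integrated intensities.

Quantifies rectangular regions of interest on gel images the way blot
densitometry is done by hand in ImageJ: the signal is the integrated
(summed) intensity inside the ROI minus the integrated intensity of a
paired, equal-area background box placed on empty membrane.  From the
FL and beta/gamma signals follow the FL:beta/gamma ratio, log2 values
for partial-correlation analyses, and fold induction relative to a
control condition.  1D lane bands are the same math with boxes placed
on lane strips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    GeometryError,
    ParameterError,
    RatioUndefinedError,
)
from .prep import GelImage, ImageStack

__all__ = [
    "ROIBox",
    "ROISignal",
    "quantify_roi",
    "quantify_stack",
    "densitometry_table",
    "compute_ratio",
    "fold_induction",
    "log2_transform",
    "validate_roi_set",
]


@dataclass(frozen=True)
class ROIBox:
    """A half-open pixel box [x0, x1) x [y0, y1) with a paired background
    box of identical dimensions anchored at (bg_x0, bg_y0)."""

    label: str
    x0: int
    y0: int
    x1: int
    y1: int
    bg_x0: int
    bg_y0: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise GeometryError(f"ROI {self.label!r} has nonpositive area")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def bg_bounds(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) of the background box."""
        return (
            self.bg_x0,
            self.bg_y0,
            self.bg_x0 + self.width,
            self.bg_y0 + self.height,
        )

    def shifted(self, dy: int, dx: int) -> "ROIBox":
        return ROIBox(
            self.label,
            self.x0 + dx,
            self.y0 + dy,
            self.x1 + dx,
            self.y1 + dy,
            self.bg_x0 + dx,
            self.bg_y0 + dy,
        )


@dataclass(frozen=True)
class ROISignal:
    """Result of quantifying one ROI on one image."""

    label: str
    raw: float  # ROI sum minus background sum, before clamping
    signal: float  # max(raw, 0)
    clamped: bool


def _boxes_overlap(
    a: tuple[int, int, int, int], b: tuple[int, int, int, int]
) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def _check_bounds(box: tuple[int, int, int, int], shape: tuple[int, int], what: str):
    x0, y0, x1, y1 = box
    h, w = shape
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise GeometryError(f"{what} box {box} outside image of shape {shape}")


def quantify_roi(image: GelImage, roi: ROIBox) -> ROISignal:
    """Background-corrected integrated density of one ROI.

    signal = sum(ROI pixels) - sum(background-box pixels); the two boxes
    have equal area by construction, so a flat background cancels
    exactly.  Negative corrected signals are clamped to zero and flagged
    rather than raised — real blots produce them routinely.
    """
    sig_box = (roi.x0, roi.y0, roi.x1, roi.y1)
    bg_box = roi.bg_bounds
    _check_bounds(sig_box, image.shape, f"ROI {roi.label!r}")
    _check_bounds(bg_box, image.shape, f"background of ROI {roi.label!r}")
    if _boxes_overlap(sig_box, bg_box):
        raise GeometryError(f"ROI {roi.label!r} overlaps its background box")
    px = image.pixels
    roi_sum = float(px[roi.y0 : roi.y1, roi.x0 : roi.x1].sum())
    bx0, by0, bx1, by1 = bg_box
    bg_sum = float(px[by0:by1, bx0:bx1].sum())
    raw = roi_sum - bg_sum
    return ROISignal(roi.label, raw, max(raw, 0.0), clamped=raw < 0.0)


def validate_roi_set(rois: Sequence[ROIBox]) -> None:
    """Check that every background box is disjoint from every signal box."""
    labels = [r.label for r in rois]
    if len(set(labels)) != len(labels):
        raise ParameterError("duplicate ROI labels")
    for r in rois:
        for other in rois:
            if _boxes_overlap(r.bg_bounds, (other.x0, other.y0, other.x1, other.y1)):
                raise GeometryError(
                    f"background of ROI {r.label!r} overlaps signal box of "
                    f"{other.label!r}"
                )


def quantify_stack(stack: ImageStack, rois: Sequence[ROIBox]) -> pd.DataFrame:
    """Quantify every ROI on every image of a stack.

    Returns one row per sample with ``<label>`` signal columns and
    ``<label>_clamped`` flags.
    """
    validate_roi_set(rois)
    rows = []
    for im in stack:
        row: dict[str, object] = {"sample_id": im.sample_id}
        for roi in rois:
            res = quantify_roi(im, roi)
            row[roi.label] = res.signal
            row[f"{roi.label}_clamped"] = res.clamped
        rows.append(row)
    return pd.DataFrame(rows)


def compute_ratio(fl_signal: float, beta_gamma_signal: float) -> float:
    """FL : beta/gamma ratio.  A zero denominator is an undefined ratio;
    the sample should be excluded from ratio analyses."""
    if fl_signal < 0 or beta_gamma_signal < 0:
        raise ParameterError("signals must be >= 0")
    if beta_gamma_signal == 0:
        raise RatioUndefinedError("beta/gamma signal is zero; ratio undefined")
    return fl_signal / beta_gamma_signal


def fold_induction(values, control_label) -> "pd.Series | dict":
    """Divide every condition's value by the control condition's value.

    The control maps to exactly 1.0.  Accepts a mapping or a pandas
    Series indexed by condition label; returns the same kind.
    """
    if isinstance(values, pd.Series):
        series = values.astype(float)
    else:
        series = pd.Series(dict(values), dtype=float)
    if control_label not in series.index:
        raise ParameterError(f"control {control_label!r} not among conditions")
    control = float(series[control_label])
    if control == 0 or not np.isfinite(control):
        raise DegenerateInputError("control value is zero or undefined")
    out = series / control
    return out if isinstance(values, pd.Series) else out.to_dict()


def log2_transform(values) -> np.ndarray:
    """Elementwise base-2 logarithm; nonpositive entries become NaN with
    a warning (excluded, never -inf)."""
    arr = np.asarray(values, dtype=float)
    bad = ~(arr > 0)
    if bad.all():
        raise DegenerateInputError("no positive values to log2-transform")
    if bad.any():
        warnings.warn(
            f"excluded {int(bad.sum())} nonpositive value(s) from log2 transform",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.full(arr.shape, np.nan)
    out[~bad] = np.log2(arr[~bad])
    return out


def densitometry_table(
    stack: ImageStack,
    fl_roi: ROIBox,
    beta_gamma_roi: ROIBox,
) -> pd.DataFrame:
    """Per-sample FL and beta/gamma signals, ratio and log2 columns.

    Samples with a zero beta/gamma signal get a NaN ratio (excluded from
    ratio analyses); nonpositive signals get NaN log2 values.
    """
    table = quantify_stack(stack, [fl_roi, beta_gamma_roi])
    fl = table[fl_roi.label].to_numpy(dtype=float)
    bg = table[beta_gamma_roi.label].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bg > 0, fl / bg, np.nan)
    out = pd.DataFrame(
        {
            "sample_id": table["sample_id"],
            "fl_signal": fl,
            "beta_gamma_signal": bg,
            "ratio": ratio,
            "fl_clamped": table[f"{fl_roi.label}_clamped"],
            "beta_gamma_clamped": table[f"{beta_gamma_roi.label}_clamped"],
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["log2_fl"] = np.where(fl > 0, np.log2(np.where(fl > 0, fl, 1.0)), np.nan)
        out["log2_beta_gamma"] = np.where(
            bg > 0, np.log2(np.where(bg > 0, bg, 1.0)), np.nan
        )
    out["log2_ratio"] = out["log2_fl"] - out["log2_beta_gamma"]
    return out
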