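"""Pixel-by-pixel Spearman correlation mapping of gel image stacks.

Across an aligned, normalized stack of n gel images, each pixel yields n
intensities; ranking those (midranks for ties) against the ranked
per-sample biological variable gives a Spearman coefficient r per pixel,

    t = r * sqrt((n - 2) / (1 - r^2)),     p = 2 * P(T_{n-2} >= |t|),

producing an r/t/p image triple.  Pixels whose intensity is constant
across samples carry no rank information and are marked undefined rather
than set to r = 0.  Thresholding p at a chosen alpha and splitting by the
sign of r yields positive/negative significance masks, whose connected
components (8-connectivity, minimum area) are the significant regions;
each region is re-scored by the same Spearman machinery on its summed
per-sample intensity.  The rendered map paints significant positive
pixels red and significant negative pixels blue, channel intensity
proportional to |r|, on neutral gray.

Per-pixel p-values are reported unadjusted; a Benjamini-Hochberg
adjusted mask is available but off by default so that raw-threshold maps
remain comparable across studies.  For very small cohorts (n <= 8) an
exact permutation p-value mode enumerates all n! covariate orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import NamedTuple

import numpy as np
from scipy.stats import rankdata, t as t_dist
from skimage.measure import label as cc_label, regionprops

from .errors import DegenerateInputError, ParameterError, StateError
from .prep import CovariateVector, ImageStack
from .stats import AssociationResult, spearman

__all__ = [
    "CorrelationMap",
    "SignificanceMasks",
    "SignificantRegion",
    "pixelwise_spearman",
    "significance_mask",
    "detect_regions",
    "region_statistic",
    "render_correlation_map",
]

_P_FLOOR = np.finfo(float).tiny  # keep p in (0, 1] even at |r| = 1
_MAX_EXACT_N = 9


@dataclass
class CorrelationMap:
    """Per-pixel Spearman r, t and two-sided p across a stack."""

    r: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n: int
    undefined_mask: np.ndarray

    @property
    def defined_mask(self) -> np.ndarray:
        return ~self.undefined_mask


class SignificanceMasks(NamedTuple):
    positive: np.ndarray
    negative: np.ndarray


@dataclass
class SignificantRegion:
    """A connected component of same-sign significant pixels."""

    mask: np.ndarray  # boolean pixel set
    sign: str  # "positive" | "negative"
    area: int
    bbox: tuple[int, int, int, int]  # (y0, x0, y1, x1), half-open
    statistic: AssociationResult | None = None
    label: str | None = None

    @property
    def region_r(self) -> float:
        return np.nan if self.statistic is None else self.statistic.r

    @property
    def region_t(self) -> float:
        return np.nan if self.statistic is None else self.statistic.t

    @property
    def region_p(self) -> float:
        return np.nan if self.statistic is None else self.statistic.p


def _check_inputs(
    stack: ImageStack, covariate: CovariateVector, require_prepped: bool
) -> tuple[np.ndarray, np.ndarray]:
    if require_prepped and not (stack.aligned and stack.normalized):
        raise StateError(
            "stack must be aligned and normalized before correlation "
            "(pass require_prepped=False to override deliberately)"
        )
    if stack.sample_ids != covariate.sample_ids:
        raise ParameterError("covariate sample order does not match the stack")
    values = covariate.values
    keep = np.isfinite(values)
    data = stack.data[keep]
    values = values[keep]
    if len(values) < 4:
        raise DegenerateInputError("fewer than 4 samples with covariate values")
    if np.unique(values).size < 2:
        raise DegenerateInputError("constant covariate")
    return data, values


def pixelwise_spearman(
    stack: ImageStack,
    covariate: CovariateVector,
    p_mode: str = "t",
    require_prepped: bool = True,
) -> CorrelationMap:
    """The core statistic: per-pixel Spearman map of a gel stack.

    Samples with a missing (NaN) covariate are dropped and the effective
    n recorded on the map.  ``p_mode="exact"`` enumerates all covariate
    permutations (n <= 8) instead of the t approximation.
    """
    if p_mode not in ("t", "exact"):
        raise ParameterError(f"unknown p_mode {p_mode!r}")
    data, values = _check_inputs(stack, covariate, require_prepped)
    n = len(values)

    ranks = rankdata(data, axis=0)
    cov_ranks = rankdata(values)

    rc = ranks - ranks.mean(axis=0)
    cc = cov_ranks - cov_ranks.mean()
    ss_pix = np.einsum("ijk,ijk->jk", rc, rc)
    ss_cov = float(np.sum(cc * cc))
    undefined = ss_pix == 0.0

    num = np.einsum("i,ijk->jk", cc, rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(ss_pix * ss_cov)
    r = np.clip(r, -1.0, 1.0)
    r[undefined] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    if p_mode == "exact":
        p = _exact_permutation_p(rc, cc, r)
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df=n - 2)
        p = np.where(np.isinf(t), _P_FLOOR, p)
        p = np.maximum(p, _P_FLOOR)
    p[undefined] = np.nan
    t[undefined] = np.nan
    return CorrelationMap(r=r, t=t, p=p, n=n, undefined_mask=undefined)


def _exact_permutation_p(
    rc: np.ndarray, cc: np.ndarray, r_obs: np.ndarray
) -> np.ndarray:
    """Two-sided exact permutation p per pixel: the fraction of covariate
    orderings whose |r| reaches the observed |r| (identity included, so
    p >= 1/n!)."""
    n = len(cc)
    if n > _MAX_EXACT_N:
        raise ParameterError(
            f"exact permutation mode enumerates n! orderings; n={n} is "
            f"beyond the supported n <= {_MAX_EXACT_N}"
        )
    perms = np.array(list(permutations(range(n))))
    cc_perm = cc[perms]  # (n!, n)
    h, w = r_obs.shape
    rc_flat = rc.reshape(len(cc), -1)
    ss_pix = np.einsum("ij,ij->j", rc_flat, rc_flat)
    ss_cov = float(np.sum(cc * cc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (cc_perm @ rc_flat) / np.sqrt(ss_pix * ss_cov)  # (n!, K)
    exceed = np.abs(r_perm) >= np.abs(r_obs.reshape(1, -1)) - 1e-12
    p = exceed.mean(axis=0).reshape(h, w)
    return p


def significance_mask(cmap: CorrelationMap, alpha: float) -> SignificanceMasks:
    """Split significant pixels by correlation sign at threshold alpha."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie strictly inside (0, 1)")
    defined = cmap.defined_mask
    sig = defined & (cmap.p < alpha)
    return SignificanceMasks(
        positive=sig & (cmap.r > 0), negative=sig & (cmap.r < 0)
    )


def bh_significance_mask(cmap: CorrelationMap, alpha: float) -> SignificanceMasks:
    """Benjamini-Hochberg-adjusted variant of :func:`significance_mask`
    over the defined pixels (optional; raw thresholds are the default
    reporting convention)."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie strictly inside (0, 1)")
    defined = cmap.defined_mask
    p = cmap.p[defined]
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    cutoff = p[order][k - 1] if k else -np.inf
    sig = np.zeros_like(defined)
    sig[defined] = p <= cutoff
    return SignificanceMasks(
        positive=sig & (cmap.r > 0), negative=sig & (cmap.r < 0)
    )


def region_statistic(
    stack: ImageStack,
    covariate: CovariateVector,
    region: np.ndarray,
    require_prepped: bool = True,
) -> AssociationResult:
    """Spearman statistic of the region-summed intensity vs the covariate.

    The per-sample region signal is the sum of the member pixels; the
    same rank machinery as the per-pixel map then gives one r/t/p triple
    for the whole region.  A zero-variance summed signal is returned as
    an undefined (NaN) result rather than an error.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != stack.shape:
        raise ParameterError("region mask shape does not match the stack")
    if not region.any():
        raise ParameterError("empty region")
    data, values = _check_inputs(stack, covariate, require_prepped)
    signals = data[:, region].sum(axis=1)
    if np.unique(signals).size < 2:
        return AssociationResult(
            method="spearman",
            r=np.nan,
            t=np.nan,
            df=len(values) - 2,
            p=np.nan,
            n=len(values),
        )
    return spearman(signals, values)


def detect_regions(
    masks: SignificanceMasks,
    min_area: int = 20,
    stack: ImageStack | None = None,
    covariate: CovariateVector | None = None,
) -> list[SignificantRegion]:
    """Connected components (8-connectivity) of the significance masks.

    Components below ``min_area`` pixels are dropped as speckle.  When a
    stack and covariate are supplied, each region is annotated with its
    region-summed Spearman statistic.
    """
    if min_area < 1:
        raise ParameterError("min_area must be >= 1")
    regions: list[SignificantRegion] = []
    for sign, mask in (("positive", masks.positive), ("negative", masks.negative)):
        labelled = cc_label(mask, connectivity=2)
        for prop in regionprops(labelled):
            if prop.area < min_area:
                continue
            member = labelled == prop.label
            stat = None
            if stack is not None and covariate is not None:
                stat = region_statistic(stack, covariate, member)
            y0, x0, y1, x1 = prop.bbox
            regions.append(
                SignificantRegion(
                    mask=member,
                    sign=sign,
                    area=int(prop.area),
                    bbox=(int(y0), int(x0), int(y1), int(x1)),
                    statistic=stat,
                )
            )
    regions.sort(key=lambda reg: -reg.area)
    return regions


def render_correlation_map(cmap: CorrelationMap, alpha: float = 0.005) -> np.ndarray:
    """RGB rendering of the map: red = significant positive correlation,
    blue = significant negative, neutral gray elsewhere.

    Channel intensity is proportional to |r|, so r = +1 renders as pure
    maximal red and r = -1 as pure maximal blue.  Returns uint8 (H, W, 3).
    """
    masks = significance_mask(cmap, alpha)
    h, w = cmap.r.shape
    img = np.full((h, w, 3), 128, dtype=np.uint8)
    mag = np.rint(255.0 * np.abs(np.nan_to_num(cmap.r))).astype(np.uint8)
    img[masks.positive] = 0
    img[masks.positive, 0] = mag[masks.positive]
    img[masks.negative] = 0
    img[masks.negative, 2] = mag[masks.negative]
    return img
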