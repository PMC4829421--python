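"""Per-cell expression quantification and rhombomere-boundary sharpness.

Expression of segmentally restricted genes (krox20 in rhombomeres 3 and
5) is quantified as the total fluorescence of each manually segmented
cell, computed on the raw 3-D stack.  Boundary sharpness is the ratio of
the length a perfectly straight ("sharp") boundary would have to the
length actually traced along the rough expression border, accumulated
slice by slice through the z-stack:

    S = sum_n d_sharp(n) / sum_n d_xy(n),   0 < S <= 1,

where d_xy is the in-plane polyline length of the boundary in slice n and
d_sharp the straight-line distance between its lateral endpoints.  The
slice thickness z cancels algebraically, so S is independent of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ranoise.noise_stats import levene_cv_comparison

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledStack",
    "BoundaryTrace",
    "SharpnessResult",
    "quantify_cells",
    "trace_boundary",
    "sharpness_index",
    "sharpness_variance",
    "stripe_masks_from_labels",
    "read_labeled_stack",
    "write_labeled_stack",
]


@dataclass(frozen=True)
class LabeledStack:
    """12-bit intensity stack with per-cell integer label masks.

    Axis order is (z, y, x); x increases posteriorly and y is the lateral
    (boundary-spanning) axis.  Label 0 is background.
    """

    intensity: np.ndarray
    labels: np.ndarray
    z_thickness: float = 1.0        # um per slice
    pixel_size: float = 1.0         # um per in-plane pixel

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity)
        labels = np.asarray(self.labels)
        if inten.shape != labels.shape or inten.ndim != 3:
            raise ValueError("intensity and labels must share a (z, y, x) shape")
        if labels.min() < 0 or not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be non-negative integers")
        if inten.min() < 0 or inten.max() > 4095:
            raise ValueError("intensity must lie within the 12-bit range [0, 4095]")
        if self.z_thickness <= 0 or self.pixel_size <= 0:
            raise ValueError("z_thickness and pixel_size must be positive")
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class BoundaryTrace:
    """In-plane boundary polyline of one z-slice.

    ``path`` is the ordered (y, x) pixel-center coordinates of the traced
    boundary; d_xy its polyline length and d_sharp the straight distance
    between its lateral endpoints, both in um.
    """

    slice_index: int
    path: np.ndarray
    d_xy: float
    d_sharp: float

    def __post_init__(self) -> None:
        if self.d_xy <= 0 or self.d_sharp <= 0:
            raise ValueError("degenerate boundary trace (non-positive length)")
        if self.d_sharp > self.d_xy + 1e-9:
            raise ValueError("d_sharp cannot exceed the traced length d_xy")


@dataclass(frozen=True)
class SharpnessResult:
    """Sharpness index with its per-slice bookkeeping."""

    boundary: str
    traces: tuple
    S: float

    def __post_init__(self) -> None:
        if not (0.0 < self.S <= 1.0 + 1e-12):
            raise ValueError(f"sharpness index out of (0, 1]: {self.S}")


# --------------------------------------------------------------------------
# per-cell quantification
# --------------------------------------------------------------------------

def quantify_cells(stack: LabeledStack) -> pd.DataFrame:
    """Total fluorescence, voxel count, and centroid per labeled cell.

    Sums raw intensity over every member voxel in 3-D (no projection or
    contrast adjustment).  Labels present in the mask but empty are
    skipped with a log entry.
    """
    labels = stack.labels
    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        raise ValueError("no non-background labels in the stack")
    totals = ndimage.sum_labels(stack.intensity, labels, index=present)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, index=present)
    centroids = ndimage.center_of_mass(stack.intensity, labels, index=present)
    rows = []
    for lab, tot, cnt, com in zip(present, totals, counts, centroids):
        if cnt == 0:
            logger.info("label %d has no voxels; skipped", lab)
            continue
        rows.append(
            {
                "label": int(lab),
                "total": float(tot),
                "n_voxels": int(cnt),
                "centroid_z": float(com[0]),
                "centroid_y": float(com[1]),
                "centroid_x": float(com[2]),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# boundary tracing
# --------------------------------------------------------------------------

def trace_boundary(
    region_mask: np.ndarray,
    side: str = "posterior",
    pixel_size: float = 1.0,
    slice_index: int = 0,
) -> BoundaryTrace:
    """Trace the anterior- or posterior-facing border of a region slice.

    For every lateral (y) row intersecting the single connected region,
    the facing border pixel is the row's minimal (anterior) or maximal
    (posterior) x member; the polyline through these pixel centers,
    ordered laterally, is the measured boundary.  Steps between adjacent
    rows contribute 1 pixel when the edge is straight and sqrt(1 + dx^2)
    when it shifts dx pixels, so a coarse staircase of equal lateral and
    axial extent approaches sqrt(2) times its endpoint distance.
    """
    mask = np.asarray(region_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("region mask must be a single 2-D slice")
    if side not in ("anterior", "posterior"):
        raise ValueError("side must be 'anterior' or 'posterior'")
    n_comp = ndimage.label(mask)[1]
    if n_comp == 0:
        raise ValueError("region mask is empty")
    if n_comp > 1:
        raise ValueError(
            f"region mask has {n_comp} disconnected components; pre-select one"
        )
    ys = np.flatnonzero(mask.any(axis=1))
    if ys.size < 2:
        raise ValueError("region spans fewer than 2 lateral rows; boundary degenerate")
    xs = np.empty(ys.size)
    for i, y in enumerate(ys):
        row = np.flatnonzero(mask[y])
        xs[i] = row.min() if side == "anterior" else row.max()
    path = np.column_stack([ys, xs]).astype(float)
    seg = np.diff(path, axis=0)
    d_xy = float(np.hypot(seg[:, 0], seg[:, 1]).sum()) * pixel_size
    d_sharp = float(np.hypot(*(path[-1] - path[0]))) * pixel_size
    return BoundaryTrace(slice_index=slice_index, path=path, d_xy=d_xy, d_sharp=d_sharp)


def sharpness_index(
    region_masks: Sequence[np.ndarray],
    side: str = "posterior",
    z_thickness: float = 1.0,
    pixel_size: float = 1.0,
    boundary: str = "",
) -> SharpnessResult:
    """Sharpness index S over a stack of per-slice region masks.

    S = (sum_n d_sharp) / (sum_n d_xy); the slice thickness multiplies
    numerator and denominator alike and cancels, which is asserted here.
    Degenerate slices (empty or 1-row regions) are skipped with a log
    entry; if every slice is degenerate an error is raised.
    """
    traces = []
    for n, mask in enumerate(region_masks):
        try:
            traces.append(trace_boundary(mask, side, pixel_size, slice_index=n))
        except ValueError as exc:
            logger.info("slice %d skipped: %s", n, exc)
    if not traces:
        raise ValueError("all slices are degenerate; sharpness undefined")
    num = sum(t.d_sharp for t in traces)
    den = sum(t.d_xy for t in traces)
    s_plain = num / den
    s_area = (num * z_thickness) / (den * z_thickness)
    assert abs(s_plain - s_area) < 1e-12  # z cancels algebraically
    return SharpnessResult(boundary=boundary, traces=tuple(traces), S=float(s_plain))


def stripe_masks_from_labels(
    stack: LabeledStack,
    threshold: float | None = None,
    n_stripes: int = 2,
) -> list:
    """Derive expression-stripe masks from per-cell totals by thresholding.

    Cells whose mean per-voxel intensity exceeds the threshold (Otsu on
    the per-cell means by default) are kept; the ``n_stripes`` largest
    connected components of the kept region, ordered by x position, are
    returned as boolean (z, y, x) masks.  Manually drawn masks are always
    accepted by the tracing functions directly, since expert segmentation
    overrides any automatic split.
    """
    from skimage.filters import threshold_otsu

    table = quantify_cells(stack)
    means = table["total"] / table["n_voxels"]
    if threshold is None:
        threshold = float(threshold_otsu(means.to_numpy()))
    keep = set(table.loc[means > threshold, "label"])
    binary = np.isin(stack.labels, list(keep))
    lab, n = ndimage.label(binary)
    if n < n_stripes:
        raise ValueError(f"found only {n} expressing components, need {n_stripes}")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    biggest = np.argsort(sizes)[::-1][:n_stripes] + 1
    coms = ndimage.center_of_mass(binary, lab, index=biggest)
    order = np.argsort([c[2] for c in coms])     # anterior to posterior
    return [lab == biggest[i] for i in order]


def sharpness_variance(
    results: Mapping[str, Sequence[SharpnessResult]],
    control: str = "WT",
) -> pd.DataFrame:
    """Mean, s.d., and variance comparison of per-embryo sharpness indices.

    Conditions contributing a single embryo are excluded with a warning;
    each remaining condition is tested against the control with Levene's
    test on its S values.
    """
    groups: dict[str, np.ndarray] = {}
    for cond, res_list in results.items():
        vals = np.array([r.S for r in res_list], dtype=float)
        if vals.size < 2:
            logger.warning("condition %r has < 2 embryos; excluded", cond)
            continue
        groups[cond] = vals
    if control not in groups:
        raise ValueError(f"control condition {control!r} missing or singleton")
    rows = []
    for cond, vals in groups.items():
        row = {
            "condition": cond,
            "n": vals.size,
            "mean_S": float(vals.mean()),
            "sd_S": float(vals.std(ddof=1)),
            "var_S": float(vals.var(ddof=1)),
        }
        if cond != control and vals.size >= 3 and groups[control].size >= 3:
            cmp = levene_cv_comparison([groups[control], vals])
            row["levene_stat_vs_control"] = cmp.levene_stat
            row["levene_p_vs_control"] = cmp.levene_p
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_labeled_stack(intensity_path, labels_path, stack: LabeledStack) -> None:
    import tifffile

    tifffile.imwrite(intensity_path, stack.intensity.astype(np.uint16),
                     photometric="minisblack")
    tifffile.imwrite(labels_path, stack.labels.astype(np.int32),
                     photometric="minisblack")


def read_labeled_stack(
    intensity_path, labels_path, z_thickness: float = 1.0, pixel_size: float = 1.0
) -> LabeledStack:
    import tifffile

    return LabeledStack(
        intensity=tifffile.imread(intensity_path),
        labels=tifffile.imread(labels_path).astype(np.int64),
        z_thickness=z_thickness,
        pixel_size=pixel_size,
    )
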