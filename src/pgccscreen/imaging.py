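"""Single-cell morphological quantification of PGCCs in fluorescence well images.

The analysis proceeds in three steps per well: (1) segment cell nuclei in the
Hoechst channel, (2) gate viability using the ethidium homodimer (dead) channel,
and (3) call polyploid giant cancer cells (PGCCs) among live cells by nuclear
area.  A well image is a 3-channel stack ordered (Hoechst, Calcein-AM,
ethidium homodimer-1).

Conventions
-----------
* Coordinates are pixel-based, origin at the top-left corner, row-major.
* Areas are reported in pixels^2; multiply by ``pixel_size**2`` for um^2.
* A live nucleus is a PGCC iff its area is >= the area threshold (inclusive).
* Dead nuclei are excluded from the PGCC / non-PGCC tallies entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import clear_border, watershed

__all__ = [
    "SegmentationParams",
    "NucleusRecord",
    "WellCounts",
    "segment_nuclei",
    "classify_viability",
    "calibrate_pgcc_threshold",
    "classify_pgcc",
    "quantify_well",
    "render_size_pseudocolor",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the three-step quantification.

    Attributes
    ----------
    threshold_method:
        ``"otsu"`` (default) or ``"fixed"``; ``fixed_threshold`` is required
        for the latter.
    min_area, max_area:
        Connected components outside ``[min_area, max_area]`` (pixels^2) are
        discarded as debris / clumps.
    split_touching:
        Apply a distance-transform watershed to separate touching nuclei.
    border_exclusion:
        Drop objects touching the image border (their area is truncated).
    dead_intensity_threshold:
        A nucleus is dead iff its mean ethidium intensity exceeds this value.
    pgcc_area_threshold:
        Absolute area cut (pixels^2) separating PGCCs from non-PGCCs.  Usually
        calibrated from control wells via :func:`calibrate_pgcc_threshold`.
    smoothing_sigma:
        Gaussian pre-smoothing applied before thresholding.
    split_min_distance:
        Minimum distance (pixels) between watershed seed maxima.
    max_foreground_fraction:
        If thresholding marks more than this fraction of pixels as
        foreground the image is treated as containing no nuclei (an empty,
        noise-only field has no bimodal histogram for Otsu to exploit).
    """

    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float | None = None
    min_area: float = 20.0
    max_area: float = 50_000.0
    split_touching: bool = True
    border_exclusion: bool = False
    dead_intensity_threshold: float = 500.0
    pgcc_area_threshold: float = 350.0
    smoothing_sigma: float = 1.0
    split_min_distance: int = 7
    max_foreground_fraction: float = 0.45
    pixel_size: float | None = None  # um per pixel, optional

    def __post_init__(self) -> None:
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when threshold_method='fixed'")
        if self.dead_intensity_threshold <= 0:
            raise ValueError("dead_intensity_threshold must be positive")


@dataclass
class NucleusRecord:
    """One segmented nucleus and its per-channel measurements."""

    label: int
    centroid: tuple[float, float]  # (row, col)
    area: float  # pixels^2
    mean_hoechst: float
    mean_calcein: float = float("nan")
    mean_ethidium: float = float("nan")
    viability: Literal["live", "dead"] | None = None
    is_pgcc: bool | None = None
    area_um2: float | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("nucleus area must be positive")


@dataclass(frozen=True)
class WellCounts:
    """Per-well live/dead/PGCC tallies; ``n_live == n_pgcc + n_nonpgcc``."""

    well_id: str
    n_live: int
    n_dead: int
    n_pgcc: int
    n_nonpgcc: int

    def __post_init__(self) -> None:
        counts = (self.n_live, self.n_dead, self.n_pgcc, self.n_nonpgcc)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_live != self.n_pgcc + self.n_nonpgcc:
            raise ValueError("n_live must equal n_pgcc + n_nonpgcc")

    @property
    def n_total_live(self) -> int:
        return self.n_live


def _check_2d(image: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 2D array, got shape {arr.shape}")
    return arr.astype(np.float64, copy=False)


def _label_image(hoechst: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary threshold + optional watershed; returns an integer label image."""
    smoothed = gaussian(hoechst, sigma=params.smoothing_sigma, preserve_range=True)
    if params.threshold_method == "fixed":
        thresh = float(params.fixed_threshold)  # type: ignore[arg-type]
    else:
        if np.ptp(smoothed) == 0:
            return np.zeros(hoechst.shape, dtype=np.int32)
        thresh = threshold_otsu(smoothed)
    mask = smoothed > thresh
    if not mask.any():
        return np.zeros(hoechst.shape, dtype=np.int32)
    if (
        params.threshold_method == "otsu"
        and mask.mean() > params.max_foreground_fraction
    ):
        # no separable foreground population (e.g. a blank, noise-only field)
        return np.zeros(hoechst.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    if params.border_exclusion:
        mask = clear_border(mask)
    if params.split_touching:
        distance = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            distance,
            min_distance=params.split_min_distance,
            labels=mask,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)
    return labels.astype(np.int32)


def segment_nuclei(
    hoechst_channel: np.ndarray,
    params: SegmentationParams | None = None,
    *,
    return_labels: bool = False,
):
    """Segment nuclei in the Hoechst channel.

    Returns a list of :class:`NucleusRecord` carrying geometry and Hoechst
    intensity only (viability and PGCC status unset).  With
    ``return_labels=True`` additionally returns the integer label image, which
    downstream steps use to measure the other channels over the same regions.
    """
    params = params or SegmentationParams()
    hoechst = _check_2d(hoechst_channel, "hoechst_channel")
    labels = _label_image(hoechst, params)
    records: list[NucleusRecord] = []
    kept = np.zeros_like(labels)
    for prop in regionprops(labels, intensity_image=hoechst):
        if not (params.min_area <= prop.area <= params.max_area):
            continue
        rec = NucleusRecord(
            label=int(prop.label),
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            area=float(prop.area),
            mean_hoechst=float(prop.intensity_mean),
        )
        if params.pixel_size is not None:
            rec.area_um2 = rec.area * params.pixel_size**2
        records.append(rec)
        kept[labels == prop.label] = prop.label
    if return_labels:
        return records, kept
    return records


def classify_viability(
    records: Sequence[NucleusRecord],
    labels: np.ndarray,
    calcein_channel: np.ndarray,
    ethidium_channel: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[NucleusRecord]:
    """Assign live/dead to each nucleus.

    A nucleus is dead iff its mean ethidium-homodimer intensity over the
    segmented region exceeds ``dead_intensity_threshold``; otherwise live.
    Ethidium positivity (rather than calcein negativity) is the dead
    criterion because ethidium stains nuclei directly, matching the nuclear
    segmentation, whereas calcein is cytoplasmic.
    """
    params = params or SegmentationParams()
    calcein = _check_2d(calcein_channel, "calcein_channel")
    ethidium = _check_2d(ethidium_channel, "ethidium_channel")
    if calcein.shape != labels.shape or ethidium.shape != labels.shape:
        raise ValueError("channel shape mismatch with label image")
    for rec in records:
        region = labels == rec.label
        rec.mean_calcein = float(calcein[region].mean())
        rec.mean_ethidium = float(ethidium[region].mean())
        rec.viability = (
            "dead" if rec.mean_ethidium > params.dead_intensity_threshold else "live"
        )
    return list(records)


def calibrate_pgcc_threshold(
    control_areas: Sequence[float], multiplier: float = 2.0
) -> float:
    """Area threshold = ``multiplier`` x median nuclear area of control cells.

    The screen gives no absolute nuclear-size cutoff, so the cutoff is
    calibrated per experiment from untreated control nuclei.  Fewer than ~20
    control areas makes the median noisy; a warning is emitted.
    """
    areas = np.asarray(list(control_areas), dtype=float)
    if areas.size == 0:
        raise ValueError("control area list is empty")
    if multiplier <= 1:
        raise ValueError("multiplier must be > 1 to separate PGCCs from controls")
    if areas.size < 20:
        warnings.warn(
            f"only {areas.size} control areas; threshold may be unstable",
            stacklevel=2,
        )
    return float(multiplier * np.median(areas))


def classify_pgcc(
    records: Sequence[NucleusRecord], area_threshold: float
) -> list[NucleusRecord]:
    """Flag live nuclei with area >= threshold as PGCCs (inclusive boundary).

    Dead nuclei keep ``is_pgcc=None`` and never enter PGCC tallies,
    regardless of size.
    """
    if area_threshold <= 0:
        raise ValueError("area_threshold must be positive")
    for rec in records:
        if rec.viability is None:
            raise ValueError("viability must be assigned before PGCC calling")
        rec.is_pgcc = (rec.area >= area_threshold) if rec.viability == "live" else None
    return list(records)


def tally_counts(records: Sequence[NucleusRecord], well_id: str = "") -> WellCounts:
    """Aggregate classified records into per-well counts."""
    n_dead = sum(1 for r in records if r.viability == "dead")
    n_pgcc = sum(1 for r in records if r.viability == "live" and r.is_pgcc)
    n_nonpgcc = sum(1 for r in records if r.viability == "live" and not r.is_pgcc)
    return WellCounts(
        well_id=well_id,
        n_live=n_pgcc + n_nonpgcc,
        n_dead=n_dead,
        n_pgcc=n_pgcc,
        n_nonpgcc=n_nonpgcc,
    )


def quantify_well(
    image3: np.ndarray,
    params: SegmentationParams | None = None,
    well_id: str = "",
    *,
    return_records: bool = False,
):
    """Run the full three-step analysis on one 3-channel well image.

    ``image3`` has shape (3, H, W) with channels ordered
    (Hoechst, Calcein-AM, ethidium homodimer-1).
    """
    params = params or SegmentationParams()
    stack = np.asarray(image3)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) image stack, got shape {stack.shape}")
    records, labels = segment_nuclei(stack[0], params, return_labels=True)
    records = classify_viability(records, labels, stack[1], stack[2], params)
    records = classify_pgcc(records, params.pgcc_area_threshold)
    counts = tally_counts(records, well_id=well_id)
    if return_records:
        return counts, records
    return counts


def render_size_pseudocolor(
    records: Sequence[NucleusRecord],
    labels: np.ndarray,
    shape: tuple[int, int] | None = None,
    cmap_name: str = "coolwarm",
) -> np.ndarray:
    """Paint each nucleus on a blue-to-red scale ordered by nuclear area.

    Larger nuclei (PGCC-like) map to red, smaller to blue; the background is
    black.  Returns an RGB float image in [0, 1].
    """
    from matplotlib import colormaps

    shape = shape or labels.shape
    if labels.shape != tuple(shape):
        raise ValueError("label image shape mismatch")
    out = np.zeros((*shape, 3), dtype=np.float64)
    if not records:
        return out
    areas = np.array([r.area for r in records], dtype=float)
    lo, hi = areas.min(), areas.max()
    cmap = colormaps[cmap_name]
    for rec in records:
        frac = 0.5 if hi == lo else (rec.area - lo) / (hi - lo)
        out[labels == rec.label] = cmap(frac)[:3]
    return out
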