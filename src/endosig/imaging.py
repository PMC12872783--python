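"""Nuclear segmentation and nuclear-to-cytoplasmic marker ratio measurement.

Quantifies transcription-factor translocation (e.g. NFAT1/2) from two-channel
fluorescence micrographs.  Nuclei are segmented from the nuclear-stain channel
(DAPI) with a median filter followed by Otsu thresholding; a perinuclear ring
built by morphological dilation of each nucleus serves as the cytoplasm proxy;
the per-cell readout is

    nc_ratio = (mean nuclear marker - background mode)
             / (mean ring marker   - background mode)

where the background estimate is the modal intensity of the marker field.
Mis-segmentation is handled by QC flags (area bounds, ring size, solidity)
rather than deletion, so every segmented object remains auditable.

Coordinate convention: row-major, 0-based pixel indices; masks are sets of
whole pixels.  "Dilation by r" throughout means the Euclidean-distance
threshold ``d <= r`` measured from the object, which coincides with binary
dilation by a disk of radius r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
from skimage.measure import regionprops


class DegenerateHistogramError(ValueError):
    """Raised when an image has fewer than two distinct intensities."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Image2D:
    """Single-channel intensity raster with optional physical pixel size.

    Parameters
    ----------
    values : ndarray
        2-D array of finite, non-negative intensities (integer or float).
    pixel_size : float, optional
        Physical pixel edge length in micrometres per pixel.
    """

    values: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {v.shape}")
        if not np.issubdtype(v.dtype, np.number):
            raise ValueError(f"non-numeric image dtype {v.dtype}")
        if np.issubdtype(v.dtype, np.floating) and not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if v.size and v.min() < 0:
            raise ValueError("image contains negative intensities")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def read(cls, path: str | Path, pixel_size: float | None = None,
             channel: int | None = None) -> "Image2D":
        """Read a single-channel TIFF/PNG image.

        For a multi-channel TIFF (channel-first stack) pass ``channel`` to
        select one plane.
        """
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path))
        arr = np.squeeze(arr)
        if arr.ndim == 3:
            if channel is None:
                raise ValueError(
                    f"{path} has {arr.shape[0]} planes; a channel index is required"
                )
            arr = arr[channel]
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
        return cls(arr, pixel_size=pixel_size)

    def write(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.values)


@dataclass
class NucleusLabels:
    """Integer label map of segmented nuclei (0 = background, 1..K nuclei)."""

    labels: np.ndarray
    threshold: float | None = None
    pixel_size: float | None = None

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class RingLabels:
    """Perinuclear ring label map; ring k belongs to nucleus k."""

    labels: np.ndarray
    gap: float = 1.0
    ring_width: float = 4.0


@dataclass
class CellRecord:
    """Per-cell measurements and QC flags for one segmented nucleus."""

    label: int
    nuclear_area_px: int
    nuclear_area_um2: float | None
    nuclear_mean: float
    ring_mean: float | None
    ring_pixels: int
    background_mode: float
    corrected_nuclear: float
    corrected_ring: float | None
    nc_ratio: float | None
    solidity: float
    qc_flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        """True when the record carries no QC flag."""
        return not self.qc_flags


@dataclass
class QCRules:
    """Automated surrogate for manual review of segmentation output.

    The original analysis removed mis-segmented cells by eye; these rules are
    a reproducible stand-in, not a reconstruction of the reviewers' criteria.
    """

    min_area_px: float = 0.0
    max_area_px: float = np.inf
    min_ring_pixels: int = 10
    min_solidity: float = 0.90


# ---------------------------------------------------------------------------
# low-level operations
# ---------------------------------------------------------------------------


def median_filter(img: Image2D, radius: int = 2) -> Image2D:
    """Median filter with a (2*radius+1)^2 square window and reflected borders.

    Border policy is symmetric reflection (edge pixel duplicated), i.e.
    ``scipy.ndimage`` mode ``"reflect"``.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(img.shape):
        raise ValueError(
            f"filter window {2 * radius + 1} exceeds image dimension {min(img.shape)}"
        )
    out = ndi.median_filter(img.values, size=2 * radius + 1, mode="reflect")
    return Image2D(out, pixel_size=img.pixel_size)


def otsu_threshold(img: Image2D | np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold maximizing between-class variance of ``value > t``.

    For integer images every occupied intensity is its own histogram bin and
    the comparison is carried out in exact integer arithmetic, so the result
    equals an exhaustive search over all candidate thresholds, with ties
    broken toward the lowest qualifying threshold.  Float images are binned
    into ``n_bins`` equal-width bins and the returned threshold is a bin edge.
    """
    v = img.values if isinstance(img, Image2D) else np.asarray(img)
    flat = v.ravel()
    if flat.size == 0:
        raise DegenerateHistogramError("empty image")
    lo = flat.min()
    hi = flat.max()
    if lo == hi:
        raise DegenerateHistogramError("degenerate histogram: single-valued image")

    if np.issubdtype(flat.dtype, np.integer):
        lo_i, hi_i = int(lo), int(hi)
        counts = np.bincount((flat - lo_i).astype(np.int64), minlength=hi_i - lo_i + 1)
        values = list(range(lo_i, hi_i + 1))
        counts = [int(c) for c in counts]
        n = sum(counts)
        s = sum(c * val for c, val in zip(counts, values))
        # maximize (s0*w1 - s1*w0)^2 / (w0*w1) over thresholds t = lo..hi-1,
        # exactly, with Python integers (background = value <= t)
        w0 = 0
        s0 = 0
        best_num, best_den, best_t = -1, 1, lo_i
        for t, c in zip(values[:-1], counts[:-1]):
            w0 += c
            s0 += c * t
            w1 = n - w0
            s1 = s - s0
            num = (s0 * w1 - s1 * w0) ** 2
            den = w0 * w1
            if num * best_den > best_num * den:  # strict: ties keep lowest t
                best_num, best_den, best_t = num, den, t
        return best_t

    edges = np.linspace(float(lo), float(hi), n_bins + 1)
    counts, _ = np.histogram(flat, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1].astype(float)
    s0 = np.cumsum(counts * centers)[:-1]
    n = flat.size
    s = float(np.sum(counts * centers))
    w1 = n - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        bcv = np.where((w0 > 0) & (w1 > 0), (s0 * w1 - (s - s0) * w0) ** 2 / (w0 * w1), -1.0)
    return float(edges[1:-1][int(np.argmax(bcv))])


def estimate_background_mode(img: Image2D | np.ndarray,
                             bin_width: float | None = None) -> float:
    """Modal intensity of the image, the background estimate.

    Integer images with ``bin_width`` None or 1 use one bin per intensity and
    return the most frequent value.  Otherwise intensities are histogrammed
    into bins of the given width anchored at a multiple of ``bin_width`` below
    the minimum, and the center of the most populated bin is returned.  Ties
    break toward the lowest bin.
    """
    v = img.values if isinstance(img, Image2D) else np.asarray(img)
    flat = v.ravel()
    if flat.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(flat.dtype, np.integer) and bin_width in (None, 1):
        counts = np.bincount(flat.astype(np.int64))
        return int(np.argmax(counts))
    if bin_width is None:
        bin_width = 1.0
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = float(flat.min())
    hi = float(flat.max())
    start = np.floor(lo / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((hi - start) / bin_width + 1e-12)))
    edges = start + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(flat, bins=edges)
    i = int(np.argmax(counts))  # first max = lowest bin on ties
    return float(edges[i] + bin_width / 2)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


def default_area_bounds(pixel_size: float | None) -> tuple[float, float]:
    """Default nuclear area gate: 100 um^2 (or 200 px) floor, 10x ceiling."""
    if pixel_size is not None:
        min_area = 100.0 / pixel_size**2
    else:
        min_area = 200.0
    return min_area, 10.0 * min_area


def segment_nuclei(
    dapi: Image2D,
    *,
    median_radius: int = 2,
    n_bins: int = 256,
    min_area: float | None = None,
    max_area: float | None = None,
    exclude_border: bool = True,
) -> NucleusLabels:
    """Segment nuclei from the nuclear-stain channel.

    Pipeline: median filter -> Otsu threshold -> binarize (``> t``) -> fill
    holes -> 8-connected components -> drop components outside
    ``[min_area, max_area]`` (pixels) -> optionally drop components touching
    the image border -> relabel 1..K.

    A single-valued (blank) field yields an empty label map rather than an
    error.  Area defaults follow :func:`default_area_bounds`.
    """
    d_min, d_max = default_area_bounds(dapi.pixel_size)
    if min_area is None:
        min_area = d_min
    if max_area is None:
        max_area = 10.0 * min_area if min_area > 0 else d_max

    filtered = median_filter(dapi, radius=median_radius)
    try:
        t = otsu_threshold(filtered, n_bins=n_bins)
    except DegenerateHistogramError:
        return NucleusLabels(np.zeros(dapi.shape, dtype=np.int32),
                             threshold=None, pixel_size=dapi.pixel_size)
    mask = filtered.values > t
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return NucleusLabels(labels.astype(np.int32), threshold=float(t),
                             pixel_size=dapi.pixel_size)

    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = (areas[1:] >= min_area) & (areas[1:] <= max_area)
    if exclude_border:
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        keep[border[border > 0]] = False

    remap = np.zeros(n + 1, dtype=np.int32)
    remap[np.flatnonzero(keep)] = np.arange(1, int(keep.sum()) + 1)
    return NucleusLabels(remap[labels], threshold=float(t),
                         pixel_size=dapi.pixel_size)


def _expand_slices(sl: tuple[slice, slice], pad: int,
                   shape: tuple[int, int]) -> tuple[slice, slice]:
    return (
        slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, shape[0])),
        slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, shape[1])),
    )


def build_rings(
    nuclei: NucleusLabels,
    gap: float = 1.0,
    ring_width: float = 4.0,
    contested: str = "exclude",
) -> RingLabels:
    """Build a perinuclear cytoplasmic ring for every nucleus.

    Candidate ring k holds the pixels with Euclidean distance
    ``gap < d <= gap + ring_width`` from nucleus k (dilation difference).
    Pixels inside any nucleus never belong to a ring.  Pixels claimed by more
    than one candidate ring are, under the default ``contested="exclude"``
    policy, removed from all rings (conservative against cross-cell
    contamination); ``contested="nearest"`` assigns them to the closest
    nucleus instead (lower label wins exact ties).  Rings may be truncated at
    the image border and may be empty; downstream QC flags empty rings.
    """
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if contested not in {"exclude", "nearest"}:
        raise ValueError(f"unknown contested-pixel policy {contested!r}")

    labels = nuclei.labels
    shape = labels.shape
    out = np.zeros(shape, dtype=np.int32)
    claims = np.zeros(shape, dtype=np.int16)
    reach = gap + ring_width
    pad = int(np.ceil(reach)) + 1
    best_d = np.full(shape, np.inf) if contested == "nearest" else None

    for k, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        win = _expand_slices(sl, pad, shape)
        m = labels[win] == k
        d = ndi.distance_transform_edt(~m)
        cand = (d > gap) & (d <= reach)
        claims[win][cand] += 1
        if contested == "nearest":
            sub_d = best_d[win]
            better = cand & (d < sub_d)
            sub_d[better] = d[better]
            out[win][better] = k
        else:
            out[win][cand] = k

    if contested == "exclude":
        out[claims > 1] = 0
    out[labels > 0] = 0
    return RingLabels(out, gap=gap, ring_width=ring_width)


# ---------------------------------------------------------------------------
# measurement and QC
# ---------------------------------------------------------------------------


def measure_cells(
    marker: Image2D,
    nuclei: NucleusLabels,
    rings: RingLabels,
    mode: float,
) -> list[CellRecord]:
    """Measure background-corrected N/C marker ratios for every nucleus.

    ``nc_ratio = (nuclear_mean - mode) / (ring_mean - mode)``.  Cells with an
    empty ring or non-positive corrected ring intensity are flagged
    (``empty_ring`` / ``nonpositive_cytoplasm``) and carry no ratio.  A
    negative corrected nuclear intensity over a positive ring still yields a
    (negative) ratio but is flagged ``negative_nuclear``.
    """
    if marker.values.shape != nuclei.labels.shape or marker.values.shape != rings.labels.shape:
        raise ValueError("marker image and label maps must share one shape")
    k = nuclei.n_labels
    if k == 0:
        return []
    idx = np.arange(1, k + 1)
    mvals = marker.values.astype(float)
    nuc_mean = ndi.mean(mvals, labels=nuclei.labels, index=idx)
    nuc_area = ndi.sum_labels(np.ones_like(mvals), labels=nuclei.labels, index=idx)
    ring_count = np.bincount(rings.labels.ravel(), minlength=k + 1)[1:]
    with np.errstate(invalid="ignore"):
        ring_mean = np.array(
            [ndi.mean(mvals, labels=rings.labels, index=i) if ring_count[i - 1] else np.nan
             for i in idx]
        )
    solidity = {p.label: p.solidity for p in regionprops(nuclei.labels)}

    px = nuclei.pixel_size if nuclei.pixel_size is not None else marker.pixel_size
    records: list[CellRecord] = []
    for i in range(k):
        lab = i + 1
        corr_n = float(nuc_mean[i]) - mode
        flags: set[str] = set()
        if ring_count[i] == 0:
            rm, corr_r, ratio = None, None, None
            flags.add("empty_ring")
        else:
            rm = float(ring_mean[i])
            corr_r = rm - mode
            if corr_r <= 0:
                ratio = None
                flags.add("nonpositive_cytoplasm")
            else:
                ratio = corr_n / corr_r
                if corr_n < 0:
                    flags.add("negative_nuclear")
        records.append(
            CellRecord(
                label=lab,
                nuclear_area_px=int(nuc_area[i]),
                nuclear_area_um2=float(nuc_area[i]) * px**2 if px else None,
                nuclear_mean=float(nuc_mean[i]),
                ring_mean=rm,
                ring_pixels=int(ring_count[i]),
                background_mode=float(mode),
                corrected_nuclear=corr_n,
                corrected_ring=corr_r,
                nc_ratio=ratio,
                solidity=float(solidity.get(lab, np.nan)),
                qc_flags=flags,
            )
        )
    return records


def qc_filter(records: Iterable[CellRecord], rules: QCRules) -> list[CellRecord]:
    """Apply automated QC rules, adding flags; nothing is deleted.

    Flags: ``area_low``, ``area_high``, ``ring_small``, ``low_solidity``
    (touching nuclei typically fail the solidity floor rather than being
    split).  Downstream summaries should use only unflagged records.
    """
    out: list[CellRecord] = []
    for rec in records:
        flags = set(rec.qc_flags)
        if rec.nuclear_area_px < rules.min_area_px:
            flags.add("area_low")
        if rec.nuclear_area_px > rules.max_area_px:
            flags.add("area_high")
        if rec.ring_pixels < rules.min_ring_pixels:
            flags.add("ring_small")
        if not np.isnan(rec.solidity) and rec.solidity < rules.min_solidity:
            flags.add("low_solidity")
        out.append(replace(rec, qc_flags=flags))
    return out


def records_to_frame(records: Sequence[CellRecord], **extra) -> pd.DataFrame:
    """Tabulate cell records; QC flags are semicolon-joined tokens.

    Keyword arguments add constant annotation columns (group, field, ...).
    """
    rows = []
    for rec in records:
        row = {
            "label": rec.label,
            "nuclear_area_px": rec.nuclear_area_px,
            "nuclear_area_um2": rec.nuclear_area_um2,
            "nuclear_mean": rec.nuclear_mean,
            "ring_mean": rec.ring_mean,
            "ring_pixels": rec.ring_pixels,
            "background_mode": rec.background_mode,
            "corrected_nuclear": rec.corrected_nuclear,
            "corrected_ring": rec.corrected_ring,
            "nc_ratio": rec.nc_ratio,
            "solidity": rec.solidity,
            "qc_flags": ";".join(sorted(rec.qc_flags)),
        }
        row.update(extra)
        rows.append(row)
    cols = ["label", "nuclear_area_px", "nuclear_area_um2", "nuclear_mean",
            "ring_mean", "ring_pixels", "background_mode", "corrected_nuclear",
            "corrected_ring", "nc_ratio", "solidity", "qc_flags", *extra.keys()]
    return pd.DataFrame(rows, columns=cols)
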