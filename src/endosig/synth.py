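"""Synthetic ground-truth data: fluorescence scenes and SILAC ratio tables.

Every downstream stage of the package is testable without external data
because its inputs can be generated here with known truth:

* :func:`generate_scene` renders a two-channel field (nuclear stain + marker)
  of non-overlapping elliptical nuclei with cytoplasmic surrounds, a
  controllable true nuclear-to-cytoplasmic marker ratio per cell, a flat
  background, and an optional noise model.  Default nuclear areas follow the
  measured endothelial cell-size distributions (wild-type-like
  1661.078 +/- 416.71 um^2; mutant-like 3004.675 +/- 254.55 um^2).
* :func:`generate_silac_tables` emits a forward/reverse label-swap pair of
  MaxQuant-dialect phosphosite tables with decoy (reverse-database),
  contaminant and low-peptide rows, a stated fraction of truly shifted sites,
  and missing ratios.

Both generators are fully determined by their spec's seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imaging import Image2D

# Nuclear area defaults (um^2): endothelial cell-size distributions measured
# for Gaq wild-type and Gaq-R183Q mutant lines.
WT_LIKE_AREA = (1661.078, 416.71)
MUTANT_LIKE_AREA = (3004.675, 254.55)

MAXQUANT_COLUMNS = [
    "Proteins",
    "Gene names",
    "Amino acid",
    "Position",
    "Localization prob",
    "Unique peptides",
    "Ratio H/L normalized",
    "Reverse",
    "Potential contaminant",
]


# ---------------------------------------------------------------------------
# image scenes
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Parameters of one synthetic two-channel field.

    Intensities are linear camera counts; the rendered images are 16-bit
    unsigned.  ``noise`` is one of ``"none"``, ``"gaussian"`` (additive,
    truncated at 0, SD ``noise_sigma``) or ``"poisson"`` (per-pixel shot
    noise on the expected intensity).
    """

    n_cells: int = 20
    field_size: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.65  # um/px
    nucleus_area_um2: tuple[float, float] = WT_LIKE_AREA  # mean, SD
    nc_ratio: tuple[float, float] = (2.0, 0.2)  # mean, SD; resampled > 0
    background_level: float = 50.0
    marker_cyto_level: float = 100.0  # cytoplasmic excess over background
    dapi_level: float = 400.0  # nuclear-stain excess is dapi_level - background
    cyto_width: float = 8.0  # px, thickness of the true cytoplasmic annulus
    aspect_range: tuple[float, float] = (1.0, 1.6)
    noise: str = "none"
    noise_sigma: float = 0.0
    crowded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("background_level", "marker_cyto_level", "dapi_level",
                     "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nucleus_area_um2[0] <= 0:
            raise ValueError("nucleus area mean must be positive")
        if self.noise not in {"none", "gaussian", "poisson"}:
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.cyto_width < 1:
            raise ValueError("cyto_width must be >= 1")
        lo, hi = self.aspect_range
        if not (1.0 <= lo <= hi):
            raise ValueError("aspect_range must satisfy 1 <= lo <= hi")


@dataclass
class SceneTruth:
    """Ground truth for one rendered scene.

    ``cells`` has one row per rendered cell: centroid (row, col), semi-axes,
    nuclear mask area in pixels, true N/C ratio.  The label maps give the
    exact nuclear and cytoplasmic-annulus masks used for rendering.
    """

    cells: pd.DataFrame
    nucleus_labels: np.ndarray
    cyto_labels: np.ndarray
    background_level: float
    seed: int

    def write(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Sample per-cell geometry with rejection sampling on overlap."""
    h, w = spec.field_size
    mean_a, sd_a = spec.nucleus_area_um2
    mean_r, sd_r = spec.nc_ratio
    cells = []
    max_attempts = 2000 * max(spec.n_cells, 1)
    attempts = 0
    while len(cells) < spec.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping nuclei in a "
                f"{h}x{w} field after {max_attempts} attempts; the requested "
                "cell density exceeds what the field can hold"
            )
        attempts += 1
        area = rng.normal(mean_a, sd_a)
        while area <= 0:
            area = rng.normal(mean_a, sd_a)
        ratio = rng.normal(mean_r, sd_r)
        while ratio <= 0:  # true ratios are strictly positive
            ratio = rng.normal(mean_r, sd_r)
        area_px = area / spec.pixel_size**2
        q = rng.uniform(*spec.aspect_range)
        a = np.sqrt(area_px * q / np.pi)  # semi-major, px
        b = a / q
        if rng.random() < 0.5:
            ar, ac = a, b  # major axis vertical
        else:
            ar, ac = b, a
        margin = a + spec.cyto_width + 2
        if 2 * margin >= min(h, w):
            raise RuntimeError(
                f"a nucleus of semi-major axis {a:.0f} px plus its annulus does "
                f"not fit in a {h}x{w} field"
            )
        r0 = rng.uniform(margin, h - margin)
        c0 = rng.uniform(margin, w - margin)
        ok = True
        for other in cells:
            if spec.crowded:
                # nuclei stay disjoint but annuli/rings may contest pixels
                d_min = a + other["semi_major"] + 2
            else:
                d_min = a + other["semi_major"] + spec.cyto_width + 2
            if np.hypot(r0 - other["row"], c0 - other["col"]) < d_min:
                ok = False
                break
        if ok:
            cells.append(
                dict(row=r0, col=c0, semi_row=ar, semi_col=ac,
                     semi_major=a, semi_minor=b, true_ratio=ratio)
            )
    return cells


def _to_uint16(expected: np.ndarray) -> np.ndarray:
    if expected.max(initial=0.0) > 65535:
        warnings.warn("intensities exceed the 16-bit range and were clipped",
                      stacklevel=3)
    return np.clip(np.rint(expected), 0, 65535).astype(np.uint16)


def generate_scene(spec: SceneSpec) -> tuple[Image2D, Image2D, SceneTruth]:
    """Render a two-channel scene and its ground truth.

    The marker channel is ``background`` everywhere, ``background +
    marker_cyto_level`` on each cytoplasmic annulus, and ``background +
    true_ratio * marker_cyto_level`` inside each nucleus, so that measuring
    the truth masks (with modal background subtraction) recovers the true
    ratio exactly up to rounding.  Noise, if any, is applied last.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    cells = _place_cells(spec, rng)

    nuc_labels = np.zeros((h, w), dtype=np.int32)
    for k, cell in enumerate(cells, start=1):
        ar, ac = cell["semi_row"], cell["semi_col"]
        r0, c0 = cell["row"], cell["col"]
        rlo = max(int(np.floor(r0 - ar)) - 1, 0)
        rhi = min(int(np.ceil(r0 + ar)) + 2, h)
        clo = max(int(np.floor(c0 - ac)) - 1, 0)
        chi = min(int(np.ceil(c0 + ac)) + 2, w)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        mask = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
        nuc_labels[rlo:rhi, clo:chi][mask] = k

    # cytoplasmic annulus: within cyto_width of the nucleus, outside all nuclei
    cyto_labels = np.zeros((h, w), dtype=np.int32)
    pad = int(np.ceil(spec.cyto_width)) + 1
    for k, sl in enumerate(ndi.find_objects(nuc_labels), start=1):
        if sl is None:
            continue
        win = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, h)),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, w)),
        )
        m = nuc_labels[win] == k
        d = ndi.distance_transform_edt(~m)
        ann = (d > 0) & (d <= spec.cyto_width)
        sub = cyto_labels[win]
        ann &= sub == 0  # crowded mode: first-come on (same-level) overlaps
        sub[ann] = k
    cyto_labels[nuc_labels > 0] = 0

    marker = np.full((h, w), spec.background_level, dtype=float)
    marker[cyto_labels > 0] = spec.background_level + spec.marker_cyto_level
    for k, cell in enumerate(cells, start=1):
        marker[nuc_labels == k] = (
            spec.background_level + cell["true_ratio"] * spec.marker_cyto_level
        )
    dapi = np.full((h, w), spec.background_level, dtype=float)
    dapi[nuc_labels > 0] = spec.dapi_level

    def _noisy(expected: np.ndarray) -> np.ndarray:
        if spec.noise == "gaussian" and spec.noise_sigma > 0:
            return np.maximum(expected + rng.normal(0, spec.noise_sigma,
                                                    expected.shape), 0.0)
        if spec.noise == "poisson":
            return rng.poisson(expected).astype(float)
        return expected

    dapi_img = Image2D(_to_uint16(_noisy(dapi)), pixel_size=spec.pixel_size)
    marker_img = Image2D(_to_uint16(_noisy(marker)), pixel_size=spec.pixel_size)

    areas = np.bincount(nuc_labels.ravel(), minlength=len(cells) + 1)
    truth_rows = [
        dict(cell=k, row=c["row"], col=c["col"], semi_major=c["semi_major"],
             semi_minor=c["semi_minor"], nuclear_area_px=int(areas[k]),
             true_ratio=c["true_ratio"])
        for k, c in enumerate(cells, start=1)
    ]
    truth = SceneTruth(
        cells=pd.DataFrame(
            truth_rows,
            columns=["cell", "row", "col", "semi_major", "semi_minor",
                     "nuclear_area_px", "true_ratio"],
        ),
        nucleus_labels=nuc_labels,
        cyto_labels=cyto_labels,
        background_level=spec.background_level,
        seed=spec.seed,
    )
    return dapi_img, marker_img, truth


def write_scene(outdir: str | Path, prefix: str, dapi: Image2D, marker: Image2D,
                truth: SceneTruth) -> dict[str, Path]:
    """Write one TIFF per channel plus the truth CSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dapi": outdir / f"{prefix}_dapi.tif",
        "marker": outdir / f"{prefix}_marker.tif",
        "truth": outdir / f"{prefix}_truth.csv",
    }
    dapi.write(paths["dapi"])
    marker.write(paths["marker"])
    truth.write(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# SILAC label-swap tables
# ---------------------------------------------------------------------------


@dataclass
class TableSpec:
    """Parameters of a synthetic forward/reverse SILAC phosphosite table pair.

    ``fraction_shifted`` sites receive a true log2 shift of
    ``+/- shift_magnitude`` (random sign).  ``ratio_noise_sd`` is the SD of
    the per-replicate log2 measurement noise, so the default shift of 0.9
    equals 3 noise SDs.  The mutant condition carries the heavy label in the
    forward experiment and the light label in the reverse experiment.
    """

    n_sites: int = 5000
    fraction_shifted: float = 0.05
    shift_magnitude: float = 0.9  # log2 units
    ratio_noise_sd: float = 0.3  # log2 units
    missing_rate: float = 0.1
    n_decoy_reverse: int = 25
    n_contaminants: int = 25
    n_low_peptide: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_shifted", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_sites", "n_decoy_reverse", "n_contaminants",
                     "n_low_peptide"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ratio_noise_sd < 0 or self.shift_magnitude < 0:
            raise ValueError("shift_magnitude and ratio_noise_sd must be >= 0")


def generate_silac_tables(
    spec: TableSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a forward/reverse label-swap pair of MaxQuant-dialect tables.

    Returns ``(forward, reverse, truth)``.  A site with true log2 shift s has
    expected forward ratio ``2**s`` (mutant heavy) and expected reverse ratio
    ``2**(-s)`` (labels swapped), before noise.  ``truth`` carries one row
    per real site with its ``shifted`` flag and true shift, plus the decoy /
    contaminant / low-peptide rows flagged by category.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    n_shift = int(round(spec.fraction_shifted * n))
    shifted = np.zeros(n, dtype=bool)
    shifted[rng.choice(n, size=n_shift, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=n)
    true_shift = np.where(shifted, signs * spec.shift_magnitude, 0.0)

    aa = rng.choice(list("STY"), size=n, p=[0.6, 0.3, 0.1])
    position = rng.integers(1, 1000, size=n)
    gene = np.array([f"GENE{i:05d}" for i in range(n)])
    protein = np.array([f"P{i:06d}" for i in range(n)])
    loc_prob = rng.uniform(0.80, 1.0, size=n).round(3)
    unique_pep = rng.integers(2, 20, size=n)

    def _replicate(orientation_sign: float) -> np.ndarray:
        log2r = orientation_sign * true_shift
        if spec.ratio_noise_sd > 0:
            log2r = log2r + rng.normal(0, spec.ratio_noise_sd, size=n)
        ratios = 2.0**log2r
        if spec.missing_rate > 0:
            ratios[rng.random(n) < spec.missing_rate] = np.nan
        return ratios

    fwd_ratio = _replicate(+1.0)
    rev_ratio = _replicate(-1.0)

    def _extra_rows(count: int, tag: str, reverse: str, contaminant: str,
                    n_pep_lo: int, n_pep_hi: int) -> pd.DataFrame:
        if count == 0:
            return pd.DataFrame(columns=MAXQUANT_COLUMNS)
        return pd.DataFrame(
            {
                "Proteins": [f"{tag}{i:04d}" for i in range(count)],
                "Gene names": [f"{tag}G{i:04d}" for i in range(count)],
                "Amino acid": rng.choice(list("STY"), size=count),
                "Position": rng.integers(1, 1000, size=count),
                "Localization prob": rng.uniform(0.80, 1.0, size=count).round(3),
                "Unique peptides": rng.integers(n_pep_lo, n_pep_hi, size=count),
                "Ratio H/L normalized": 2.0 ** rng.normal(0, max(spec.ratio_noise_sd, 0.1), size=count),
                "Reverse": reverse,
                "Potential contaminant": contaminant,
            }
        )

    def _table(ratios: np.ndarray) -> pd.DataFrame:
        base = pd.DataFrame(
            {
                "Proteins": protein,
                "Gene names": gene,
                "Amino acid": aa,
                "Position": position,
                "Localization prob": loc_prob,
                "Unique peptides": unique_pep,
                "Ratio H/L normalized": ratios,
                "Reverse": "",
                "Potential contaminant": "",
            }
        )
        extras = [
            _extra_rows(spec.n_decoy_reverse, "REV", "+", "", 2, 20),
            _extra_rows(spec.n_contaminants, "CON", "", "+", 2, 20),
            _extra_rows(spec.n_low_peptide, "LOWPEP", "", "", 1, 2),
        ]
        table = pd.concat([base, *[e for e in extras if len(e)]],
                          ignore_index=True)
        return table[MAXQUANT_COLUMNS]

    forward = _table(fwd_ratio)
    reverse = _table(rev_ratio)

    truth = pd.DataFrame(
        {
            "Proteins": forward["Proteins"],
            "Gene names": forward["Gene names"],
            "Amino acid": forward["Amino acid"],
            "Position": forward["Position"],
            "category": (["site"] * n + ["decoy"] * spec.n_decoy_reverse
                         + ["contaminant"] * spec.n_contaminants
                         + ["low_peptide"] * spec.n_low_peptide),
            "shifted": np.concatenate(
                [shifted, np.zeros(len(forward) - n, dtype=bool)]
            ),
            "true_shift_log2": np.concatenate(
                [true_shift, np.zeros(len(forward) - n)]
            ),
        }
    )
    return forward, reverse, truth


def write_silac_tables(outdir: str | Path, forward: pd.DataFrame,
                       reverse: pd.DataFrame, truth: pd.DataFrame,
                       prefix: str = "silac") -> dict[str, Path]:
    """Write the tab-delimited forward/reverse tables plus the truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "forward": outdir / f"{prefix}_forward.txt",
        "reverse": outdir / f"{prefix}_reverse.txt",
        "truth": outdir / f"{prefix}_truth.csv",
    }
    forward.to_csv(paths["forward"], sep="\t", index=False, na_rep="NaN")
    reverse.to_csv(paths["reverse"], sep="\t", index=False, na_rep="NaN")
    truth.to_csv(paths["truth"], index=False)
    return paths
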