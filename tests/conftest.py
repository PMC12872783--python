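"""Shared fixtures: small synthetic scenes and the ratio-recovery experiment."""

from __future__ import annotations

import numpy as np
import pytest

from endosig import imaging
from endosig.synth import SceneSpec, generate_scene

# area gate for scenes rendered from the default nuclear-area distribution
# (mean 1661 um^2 at 0.65 um/px -> ~3900 px nuclei)
SCENE_AREA_BOUNDS = dict(min_area=800, max_area=30000)


def measure_scene(dapi, marker, *, gap=1, ring_width=4, qc=True):
    """Run the standard imaging chain on one scene; returns cell records."""
    nuclei = imaging.segment_nuclei(dapi, **SCENE_AREA_BOUNDS)
    rings = imaging.build_rings(nuclei, gap=gap, ring_width=ring_width)
    mode = imaging.estimate_background_mode(marker)
    records = imaging.measure_cells(marker, nuclei, rings, mode)
    if qc:
        rules = imaging.QCRules(min_area_px=SCENE_AREA_BOUNDS["min_area"],
                                max_area_px=SCENE_AREA_BOUNDS["max_area"])
        records = imaging.qc_filter(records, rules)
    return records


def measured_ratios(dapi, marker, **kw) -> np.ndarray:
    recs = measure_scene(dapi, marker, **kw)
    return np.array([r.nc_ratio for r in recs if r.ok and r.nc_ratio is not None])


def recovery_spec(true_ratio: float, noise_sigma: float, seed: int,
                  n_cells: int = 20) -> SceneSpec:
    """One field of the parameter-recovery study conditions."""
    return SceneSpec(
        n_cells=n_cells,
        nc_ratio=(true_ratio, 0.0),
        noise="gaussian" if noise_sigma > 0 else "none",
        noise_sigma=noise_sigma,
        seed=seed,
    )


def run_recovery(noise_sigma: float, ratios=(0.5, 1.0, 2.0, 4.0),
                 n_cells_total: int = 100, seed0: int = 100) -> dict[float, np.ndarray]:
    """Measure N/C ratios over synthetic scenes at several true ratios.

    ``n_cells_total`` cells per condition, rendered as fields of 20 cells.
    Noise sigma 5 corresponds to 5% of the cytoplasmic signal level (100).
    """
    n_fields = n_cells_total // 20
    out: dict[float, np.ndarray] = {}
    for gi, r in enumerate(ratios):
        vals = []
        for f in range(n_fields):
            spec = recovery_spec(r, noise_sigma, seed=seed0 + 97 * gi + f)
            dapi, marker, _ = generate_scene(spec)
            vals.append(measured_ratios(dapi, marker))
        out[r] = np.concatenate(vals)
    return out


@pytest.fixture(scope="session")
def recovery_noisy():
    """Measured ratios at truths {0.5,1,2,4}, 100 cells each, 5% noise."""
    return run_recovery(noise_sigma=5.0)


@pytest.fixture(scope="session")
def recovery_clean():
    """Same conditions without noise."""
    return run_recovery(noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic noiseless default scene plus its truth."""
    return generate_scene(SceneSpec(n_cells=12, seed=42))
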