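import numpy as np
import pytest

from neflow.preprocess import (
    bleedthrough_correct,
    build_fields,
    extract_traces,
    soma_masks_from_labels,
)
from neflow.synth import SimulationConfig, simulate_run


@pytest.fixture(scope="session")
def bursty_run():
    """One shared small recording with bursty perineuronal release.

    Used by synchrony/spatial/stats tests that need a realistic movie with
    ground truth; generated once per session. Returns the clean NE field,
    ground truth, config, field geometry and extracted standardized traces
    (movie itself is dropped to bound memory).
    """
    cfg = SimulationConfig(
        fov_px=(96, 96), duration_s=180.0, n_cells=9,
        varicosities_at_cells=True, n_varicosities=12, seed=1,
    )
    movie, ne, truth = simulate_run(cfg)
    corrected = bleedthrough_correct(movie)
    del movie
    geom = build_fields(soma_masks_from_labels(truth.soma_labels),
                        radius_um=cfg.annulus_radius_um, px_um=cfg.px_um)
    traces = extract_traces(corrected, geom)
    del corrected
    return {"ne": ne, "truth": truth, "cfg": cfg, "geom": geom,
            "traces": traces}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
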