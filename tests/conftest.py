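import dataclasses

import numpy as np
import pytest

import subfrac as sf


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, unblurred scene with zero background: exact-oracle regime."""
    params = sf.SceneParams(noise_model="none", apply_psf=False,
                            background_level=0.0, seed=3)
    stack, truth = sf.generate_scene(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Scene at generator defaults (PSF blur + Poisson noise)."""
    params = sf.SceneParams(seed=11)
    stack, truth = sf.generate_scene(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def control_thresholds():
    """Thresholds derived from simulated negative-control scenes (k=3)."""
    controls = []
    for s in range(4):
        params = dataclasses.replace(
            sf.SceneParams(), n_synaptic=0, n_extrasynaptic=0,
            n_intracellular=0, n_marker_only=0, ring_amplitude=0.0,
            seed=900 + s,
        )
        controls.append(sf.generate_scene(params)[0])
    return sf.ThresholdSpec(
        receptor_threshold=sf.derive_threshold(controls, "receptor", 3.0),
        marker_threshold=sf.derive_threshold(controls, "marker", 3.0),
        method="control_mean_plus_k_sd", k=3.0,
    )


@pytest.fixture
def zero_thresholds():
    return sf.ThresholdSpec(0.0, 0.0)


def brute_force_counts(receptor, marker, thr_r, thr_m):
    """Triple-loop per-plane pixel counts: the independent counting oracle."""
    nz, ny, nx = receptor.shape
    rows = []
    for z in range(nz):
        r_px = m_px = c_px = 0
        for y in range(ny):
            for x in range(nx):
                r = receptor[z, y, x] > thr_r
                m = marker[z, y, x] > thr_m
                r_px += int(r)
                m_px += int(m)
                c_px += int(r and m)
        rows.append((z, r_px, m_px, c_px))
    return rows
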