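"""Shared fixtures: expensive simulated scans are session-scoped."""

import numpy as np
import pytest

from retrogate import (PhantomConfig, RunConfig, ScanGeometry, gate,
                       make_template, simulate_scan)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    """The default experiment: 60 s noiseless scan of the default phantom,
    root seed 1."""
    return RunConfig(seed=1).seeded()


@pytest.fixture(scope="session")
def default_stream(default_config):
    return simulate_scan(default_config.phantom, default_config.geometry)


@pytest.fixture(scope="session")
def default_template(default_config, default_stream):
    return make_template(default_config, default_stream)


@pytest.fixture(scope="session")
def default_gating(default_stream, default_template, default_config):
    return gate(default_stream, default_template, default_config.gating)


@pytest.fixture(scope="session")
def static_sinogram():
    """720 noiseless views of the phantom frozen at t=0 (no motion)."""
    from retrogate import forward_project, render_thorax

    cfg = PhantomConfig()
    geo = ScanGeometry()
    img = render_thorax(cfg, 0.0).values
    angles = np.arange(720) * 0.5
    sino = np.array([
        forward_project(img, a, geo, cfg.pixel_mm) for a in angles
    ])
    return {"image": img, "sino": sino, "angles": angles,
            "config": cfg, "geometry": geo}


@pytest.fixture(scope="session")
def disk_sinogram():
    """720 noiseless views of a uniform off-origin-free disk."""
    from retrogate import forward_project

    cfg = PhantomConfig()
    geo = ScanGeometry()
    n = cfg.grid_n
    c = (np.arange(n) - (n - 1) / 2) * cfg.pixel_mm
    xx, yy = np.meshgrid(c, c)
    img = np.where(xx ** 2 + yy ** 2 <= 10.0 ** 2, 0.02, 0.0)
    angles = np.arange(720) * 0.5
    sino = np.array([
        forward_project(img, a, geo, cfg.pixel_mm) for a in angles
    ])
    return {"image": img, "sino": sino, "angles": angles,
            "config": cfg, "geometry": geo}


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Complete default pipeline run (simulate->gate->recon->metrics),
    with wall-clock time recorded."""
    import time

    from retrogate import run

    out = tmp_path_factory.mktemp("full_run")
    cfg = RunConfig(seed=1, out_dir=str(out), log_level="warning")
    t0 = time.time()
    report = run(cfg)
    elapsed = time.time() - t0
    return {"report": report, "elapsed_s": elapsed, "config": cfg,
            "out": out}
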