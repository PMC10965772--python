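"""Shared fixtures: phantoms, trained models and one reference pipeline run.

Heavy artefacts are session-scoped.  The "coarse" phantom (~300 elements) is
for fast simulation-loop tests; the "fine" one (~4k elements) for forward-
accuracy and reconstruction-quality checks.
"""

import numpy as np
import pytest

from avieit import (
    Contour,
    ContourSet,
    ScenarioConfig,
    build_phantom,
    default_chicken_contours,
    make_pattern,
    reconstruct,
    simulate_recording,
    train_greit,
)


def circle(r=1.0, centre=(0.0, 0.0), n=360, name=""):
    th = 2 * np.pi * np.arange(n) / n
    return Contour(
        np.column_stack([centre[0] + r * np.cos(th), centre[1] + r * np.sin(th)]),
        name,
    )


def disk_contour_set(n=360):
    """Unit-disk outer contour with small interior ROIs (for solver tests)."""
    return ContourSet(
        outer=circle(1.0, n=n, name="outer"),
        lung_r=circle(0.08, (-0.3, 0.45), n=36, name="lung_r"),
        lung_l=circle(0.08, (0.3, 0.45), n=36, name="lung_l"),
        cardiac=circle(0.12, (0.0, -0.25), n=36, name="cardiac"),
    )


@pytest.fixture(scope="session")
def chicken():
    return default_chicken_contours()


@pytest.fixture(scope="session")
def pattern():
    return make_pattern(32, 0)


@pytest.fixture(scope="session")
def coarse_phantom(chicken):
    return build_phantom(chicken, mesh_size=6.5)


@pytest.fixture(scope="session")
def coarse_model(coarse_phantom, pattern):
    return train_greit(coarse_phantom, pattern, n_targets=300, seed=0)


@pytest.fixture(scope="session")
def fine_phantom(chicken):
    return build_phantom(chicken, mesh_size=1.9)


@pytest.fixture(scope="session")
def fine_model(fine_phantom, pattern):
    return train_greit(fine_phantom, pattern, n_targets=1000, seed=0)


@pytest.fixture(scope="session")
def default_run(fine_phantom, fine_model):
    """One default 2-min scenario simulated and reconstructed on the fine
    phantom; the shared substrate for distribution-variable checks."""
    cfg = ScenarioConfig(seed=42)
    rec, truth = simulate_recording(fine_phantom, cfg)
    stream = reconstruct(
        fine_model, rec.voltages[rec.ref_frame], rec.voltages, fps=rec.fps
    )
    return cfg, rec, truth, stream


@pytest.fixture(scope="session")
def coarse_sim(coarse_phantom, coarse_model):
    """A short coarse-phantom recording + image stream for pipeline tests."""
    cfg = ScenarioConfig(duration_s=60.0, seed=11)
    rec, truth = simulate_recording(coarse_phantom, cfg)
    stream = reconstruct(
        coarse_model, rec.voltages[rec.ref_frame], rec.voltages, fps=rec.fps
    )
    return cfg, rec, truth, stream
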