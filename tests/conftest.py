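"""Shared fixtures.

Two scales are used:

* ``small`` — a 128-pixel, 7x7-LED system for unit-level engine tests
  (seconds each);
* the reference 512-pixel, 15x15-LED system for behavioural and acceptance
  tests.  Reconstruction runs at reference scale are cached per
  (stack, algorithm, options) for the whole session, because several tests
  score different aspects of the same deterministic run.
"""

from __future__ import annotations

import numpy as np
import pytest

from fpmrecon import (
    ReconConfig,
    SceneSpec,
    SystemGeometry,
    run_reconstruction,
    sample_random_coeffs,
    simulate_dataset,
)
from fpmrecon.geometry import frequency_grid


@pytest.fixture(scope="session")
def geom_small() -> SystemGeometry:
    return SystemGeometry(led_rows=7, led_cols=7, hr_size=128)


@pytest.fixture(scope="session")
def grid_small(geom_small):
    return frequency_grid(geom_small)


@pytest.fixture(scope="session")
def small_scene() -> SceneSpec:
    return SceneSpec(size=128, seed=7)


@pytest.fixture(scope="session")
def small_stack_plain(geom_small, small_scene):
    """Aberration-free small capture stack."""
    return simulate_dataset(small_scene, geom_small, None)


@pytest.fixture(scope="session")
def small_stack_aberrated(geom_small, small_scene):
    return simulate_dataset(small_scene, geom_small,
                            sample_random_coeffs(11, jmax=15, bound=0.1))


# ----------------------------------------------------------------------
# reference-scale fixtures
# ----------------------------------------------------------------------
@pytest.fixture(scope="session")
def ref_geometry() -> SystemGeometry:
    return SystemGeometry()


@pytest.fixture(scope="session")
def ref_scene() -> SceneSpec:
    return SceneSpec()


@pytest.fixture(scope="session")
def ref_stack_plain(ref_geometry, ref_scene):
    """Reference-scale stack with no aberration."""
    return simulate_dataset(ref_scene, ref_geometry, None)


@pytest.fixture(scope="session")
def ref_stacks_aberrated(ref_geometry, ref_scene):
    """Reference-scale stacks under seeded hybrid aberrations (seeds 1-3)."""
    return {seed: simulate_dataset(ref_scene, ref_geometry,
                                   sample_random_coeffs(seed, jmax=15, bound=0.2))
            for seed in (1, 2, 3)}


@pytest.fixture(scope="session")
def run_cached():
    """Session-wide cache of deterministic reconstruction runs.

    ``get(tag, stack, algorithm, **config_kwargs)`` — ``tag`` identifies the
    stack (stacks themselves are unhashable).
    """
    cache: dict = {}

    def get(tag: str, stack, algorithm: str, **kwargs):
        key = (tag, algorithm, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = run_reconstruction(
                stack, ReconConfig(algorithm=algorithm, **kwargs))
        return cache[key]

    return get
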