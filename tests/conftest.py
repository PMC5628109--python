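"""Shared fixtures: phantoms are rendered once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

import cacscore as cs


@pytest.fixture(scope="session")
def clean_spec() -> cs.PhantomSpec:
    """Noise-free, blur-free phantom with two lesions and distractors."""
    return cs.PhantomSpec(
        lesions=(
            cs.LesionSpec("LAD", 0.30, 3.5, 500.0),
            cs.LesionSpec("RCA", 0.70, 3.0, 300.0),
        ),
        aortic_calcs=(cs.AorticCalcSpec(0.5, 2.5, 450.0),),
        noise_sd_csct=0.0,
        noise_sd_ctac=0.0,
        motion_blur_mm=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def clean_pair(clean_spec):
    return cs.generate_pair(clean_spec)


@pytest.fixture(scope="session")
def default_pair(clean_spec):
    """Same anatomy under default noise and motion blur."""
    from dataclasses import replace

    spec = replace(clean_spec, noise_sd_csct=10.0, noise_sd_ctac=25.0,
                   motion_blur_mm=3.0)
    return cs.generate_pair(spec)


@pytest.fixture(scope="session")
def template():
    return cs.make_template()


@pytest.fixture(scope="session")
def small_cohort():
    return cs.generate_cohort(8, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
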