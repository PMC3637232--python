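"""Shared fixtures: one multi-site study generated once per session.

Hyperparameter grids used in tests are decimated versions of the full
search ranges so the suite runs at desk scale; the pipeline under test is
unchanged.
"""

import numpy as np
import pytest

from icamam import io_roi, synthetic_data as sd

# Coarse sweep grids for desk-scale classifier selection.
COARSE_GAMMA_EXPS = np.arange(-9.0, 0.1, 2.0)
COARSE_C_EXPS = np.arange(-1.0, 6.1, 2.0)


@pytest.fixture(scope="session")
def study():
    """Default four-site study at strong effect: (cases, profiles)."""
    return sd.generate_study(effect=1.0, seed=0)


@pytest.fixture(scope="session")
def prototypes(study):
    """Prototypes cut from the session study at 32 and 64 px."""
    cases, profiles = study
    return io_roi.extract_prototypes(cases, profiles, sizes=(32, 64), seed=0)


@pytest.fixture(scope="session")
def single_site_strong():
    """One-site dataset, ~400 prototypes per class, strong effect, 32 px."""
    prof = sd.DEFAULT_PROFILES[0]
    cases = sd.generate_site_dataset(prof, 200, 200, 200, effect=1.0, seed=3)
    return io_roi.extract_prototypes(cases, {prof.name: prof},
                                     sizes=(32,), seed=3)[32]
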