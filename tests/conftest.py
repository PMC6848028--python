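import logging

import numpy as np
import pytest

from bbpcmap import pipeline as pl
from bbpcmap import synth

logging.getLogger("bbpcmap").setLevel(logging.ERROR)

SMALL_SHAPE = (48, 44, 16)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-grid configuration keeping every geometric element present."""
    return synth.SimulationConfig(n_subjects=1, shape=SMALL_SHAPE, seed=11)


@pytest.fixture(scope="session")
def noiseless_subject(small_config):
    cfg = synth.noiseless(small_config)
    return synth.make_subject(cfg, 11)


@pytest.fixture(scope="session")
def noisy_subject(small_config):
    return synth.make_subject(small_config, 11)


@pytest.fixture(scope="session")
def fitted_noiseless(noiseless_subject):
    """(subject, M0Map, T1Map) for the noiseless small subject."""
    from bbpcmap.recovery import fit_recovery_volume

    s = noiseless_subject
    fit_mask = s.masks["brain"] | s.masks["blood"] | pl._vial_union(s.masks)
    m0, t1 = fit_recovery_volume(s.tr_series, fit_mask)
    return s, m0, t1


def small_pipeline_options(**overrides):
    """Pipeline options scaled to the reduced test grid."""
    defaults = dict(erode_px=1, center_slices=8)
    defaults.update(overrides)
    return pl.PipelineOptions(**defaults)
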