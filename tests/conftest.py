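"""Shared fixtures: small deterministic designs, patches and datasets."""

import numpy as np
import pytest

from lamfmri.design import ExperimentParams, build_run_design, schedule_targets
from lamfmri.synth import (default_ground_truth, make_cortical_patch,
                           simulate_vertex_betas)

SMALL_ROI_SIZES = {"A1": 60, "PT": 40, "V1": 60, "V23": 40}


@pytest.fixture(scope="session")
def default_design():
    return build_run_design(ExperimentParams(), rng_seed=11)


@pytest.fixture(scope="session")
def default_schedule(default_design):
    return schedule_targets(default_design, rng_seed=12)


@pytest.fixture(scope="session")
def small_patch():
    return make_cortical_patch(SMALL_ROI_SIZES, rng_seed=7)


@pytest.fixture(scope="session")
def noisy_dataset(small_patch, default_design):
    """One subject simulated under the default (noisy) study conditions."""
    return simulate_vertex_betas(small_patch, default_ground_truth(),
                                 default_design, 1, rng_seed=21)[0]


def clean_ground_truth(**roi_overrides):
    """Noise-free ground truth with flat depth gain and no attention gain.

    Used when a planted laminar shape must be recovered exactly: the
    multiplicative depth and attention gains are disabled so the planted
    (C*, L*) pass through the pipeline unchanged.
    """
    from lamfmri.synth import ROITruth, default_ground_truth

    def flat(preferred, **kw):
        base = dict(preferred=preferred, activation_patchy_sd=0.0,
                    deact_C_sd=0.0, deact_L_sd=0.0, mod_sd=0.0, mod_L_sd=0.0,
                    rho_mod_deact=0.0, attention_gain=0.0,
                    depth_gain_slope=0.0)
        base.update(kw)
        return ROITruth(**base)

    rois = {"A1": flat("A"), "PT": flat("A"),
            "V1": flat("V", deact_L=-0.3), "V23": flat("V", deact_L=-0.3)}
    for name, kw in roi_overrides.items():
        rois[name] = flat(**kw)
    return default_ground_truth(
        rois=rois, beta_noise_sd=0.0, run_offset_sd=0.0, day_offset_sd=0.0,
        subject_deact_C_sd=0.0, subject_deact_L_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_dataset(small_patch, default_design):
    return simulate_vertex_betas(small_patch, clean_ground_truth(),
                                 default_design, 1, rng_seed=22)[0]
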