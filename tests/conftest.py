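"""Shared fixtures: phantoms, responses, fitted fields, tractograms.

Heavy artifacts are session-scoped and reused across modules to keep the
suite inside its runtime budget.
"""

from dataclasses import replace

import numpy as np
import pytest

from lesionpipe.csd import SS3TOptions, estimate_responses, fit_ss3t_volume, signal_fractions
from lesionpipe.phantom import (RegionSpec, build_phantom, default_phantom_spec,
                                make_gradient_table)
from lesionpipe.tracking import TrackingParams, generate_tractogram


@pytest.fixture(scope="session")
def gtab138():
    return make_gradient_table(10, 64, [1500.0, 3000.0])


@pytest.fixture(scope="session")
def pure_phantom12():
    """12^3 phantom with pure-compartment tissues (for response oracles)."""
    spec = default_phantom_spec(grid_shape=(12, 12, 12),
                                bundle_fractions=(0.0, 0.0, 1.0))
    bg = dict(spec.background_tissue)
    bg["gm"] = RegionSpec(fractions=(0.0, 1.0, 0.0), lo=bg["gm"].lo,
                          hi=bg["gm"].hi)
    spec = replace(spec, background_tissue=bg)
    return spec, *build_phantom(spec)


@pytest.fixture(scope="session")
def pure_responses12(pure_phantom12):
    _, dwi, truth = pure_phantom12
    return estimate_responses(dwi, truth.tissue_masks, lmax=8)


@pytest.fixture(scope="session")
def phantom20():
    """Default 20^3 straight-bundle phantom (no lesion)."""
    spec = default_phantom_spec(grid_shape=(20, 20, 20))
    return spec, *build_phantom(spec)


@pytest.fixture(scope="session")
def fitted20(phantom20):
    """(responses, fod, weights, fractions) on the 20^3 phantom."""
    _, dwi, truth = phantom20
    responses = estimate_responses(dwi, truth.tissue_masks, lmax=8)
    fod, weights = fit_ss3t_volume(dwi, responses)
    fractions = signal_fractions(weights, affine=dwi.affine,
                                 mask=dwi.brain_mask)
    return responses, fod, weights, fractions


@pytest.fixture(scope="session")
def tract2000(phantom20, fitted20):
    _, dwi, _ = phantom20
    _, fod, _, _ = fitted20
    params = TrackingParams(target_count=2000)
    return params, generate_tractogram(fod, dwi.brain_mask, params, 42)


@pytest.fixture(scope="session")
def lesioned20():
    """20^3 bundle phantom with an interior lesion, fitted and tracked."""
    spec = default_phantom_spec(grid_shape=(20, 20, 20), lesion_radius=3.4)
    dwi, truth = build_phantom(spec)
    responses = estimate_responses(dwi, truth.tissue_masks, lmax=8)
    fod, weights = fit_ss3t_volume(dwi, responses)
    fractions = signal_fractions(weights, affine=dwi.affine,
                                 mask=dwi.brain_mask)
    params = TrackingParams(target_count=1500)
    tract = generate_tractogram(fod, dwi.brain_mask, params, 7)
    return dwi, truth, fod, fractions, tract
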