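"""Shared fixtures: small deterministic stacks and profile collections."""

import numpy as np
import pandas as pd
import pytest

from organoidscreen import (AcquisitionParams, ImageStack, PhenotypeParams,
                            generate_well_stack)
from organoidscreen.simulate import render_organoids, _apply_noise


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_acq():
    return AcquisitionParams(frame_shape=(192, 192))


@pytest.fixture(scope="session")
def default_well(acq):
    """One default-parameter well: 5 in-focus organoids, theta 0."""
    stack, gt = generate_well_stack(
        PhenotypeParams(n_organoids=5), acq, seed=7, well_id="A01")
    return stack, gt


def make_fixture_stack(records, acq, seed=0, well_id="FIX"):
    """Render an exact geometry table into a noisy two-channel stack."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(records)
    actin, dapi = render_organoids(df, acq, rng)
    return ImageStack(
        nuclei_channel=_apply_noise(dapi, acq, rng),
        actin_channel=_apply_noise(actin, acq, rng),
        acquisition=acq, well_id=well_id), df


def organoid_record(organoid_id=1, x=128.0, y=128.0, z=12.5,
                    radius_um=70.0, lumen_radius_um=35.0, n_nuclei=0,
                    in_focus=True, theta=0.0):
    return dict(organoid_id=organoid_id, x=x, y=y, z=z,
                radius_um=radius_um, lumen_radius_um=lumen_radius_um,
                n_nuclei=n_nuclei, in_focus=in_focus, theta=theta)
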