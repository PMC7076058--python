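"""Shared fixtures: phantoms, analytic volumes, and the full 7-montage run.

The expensive end-to-end solve (seven configurations on the default 4 mm
phantom) is computed once per session and shared by the acceptance and
solver-property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ttfplan import (
    CONFIGURATIONS,
    LabelVolume,
    PhantomSpec,
    Tissue,
    VoxelGrid,
    build_phantom,
    combine_channels,
    pqm,
)
from ttfplan.phantom import mini_spec
from ttfplan.pipeline import make_fixtures, solve_configuration


@pytest.fixture(scope="session")
def default_phantom():
    """Default 4 mm head phantom with its GTV/cerebellum masks."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def mini_phantom():
    """Reduced-size head for fast end-to-end tests."""
    return build_phantom(mini_spec())


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def flat_slab():
    """A flat scalp slab for surface-geometry oracles (planar top at z)."""
    grid = VoxelGrid(shape=(41, 41, 24), spacing=(2.0, 2.0, 2.0), origin=(-40.0, -40.0, 0.0))
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[:, :, :12] = Tissue.SCALP  # top surface at z = 23 mm (last tissue center 22)
    return LabelVolume(grid, labels)


@pytest.fixture(scope="session")
def full_run(default_phantom):
    """Solve all seven montage configurations on the default phantom.

    Returns masks, per-configuration combined |E|/|J| maps and PQM
    records, and the raw SUPRATENTORIAL channel solutions for the
    solver-invariant tests.
    """
    volume, masks = default_phantom
    out = {"volume": volume, "masks": masks, "configs": {}}
    for name in CONFIGURATIONS:
        layout, model, sol_ap, sol_lr = solve_configuration(volume, name)
        e_mag = combine_channels(sol_ap, sol_lr, "average", "E")
        cd_mag = combine_channels(sol_ap, sol_lr, "average", "CD")
        entry = {
            "layout": layout,
            "e_mag": e_mag,
            "cd_mag": cd_mag,
            "gtv_mean_e": float(e_mag[masks["GTV"].member].mean()),
            "cb_mean_e": float(e_mag[masks["CEREBELLUM"].member].mean()),
            "records": [
                pqm(e_mag, cd_mag, masks[roi], name, roi=roi)
                for roi in ("GTV", "CEREBELLUM")
            ],
        }
        if name == "SUPRATENTORIAL":
            entry["solutions"] = (sol_ap, sol_lr)
            entry["model"] = model
        out["configs"][name] = entry
    return out
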