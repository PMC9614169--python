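"""Shared fixtures: one mid-size phantom and its derived models, built once."""

from __future__ import annotations

import numpy as np
import pytest

import tkp
from tkp.pipeline import build_perfusion_model
from tkp.territories import estimate_territories


@pytest.fixture(scope="session")
def bundle3():
    """Default 3-segment, depth-2 phantom at 1 mm spacing."""
    return tkp.generate_phantom(rng_seed=7)


@pytest.fixture(scope="session")
def model3(bundle3):
    """Full pipeline (skeleton -> tree -> territories) on bundle3."""
    tree, tmap = build_perfusion_model(
        bundle3.kidney, bundle3.sinus_ucs, bundle3.vessels, bundle3.truth.root_hint
    )
    return tree, tmap


@pytest.fixture(scope="session")
def truth_map3(bundle3):
    """Territory map built from the phantom's truth-labeled vessels."""
    return estimate_territories(
        bundle3.parenchyma(),
        bundle3.painted_vessels_truth("lobar"),
        bundle3.truth.lobar_to_segment(),
    )


def brute_force_nearest_seed(seeds: tkp.LabelVolume, domain: tkp.LabelVolume) -> np.ndarray:
    """O(voxels x seeds) oracle for nearest-seed assignment.

    Squared distances within 1e-6 mm^2 of the minimum are ties; the lowest
    label among tied seeds wins — the package-wide rule.
    """
    sp = np.asarray(seeds.spacing)
    pts = np.argwhere(seeds.data > 0)
    labs = seeds.data[pts[:, 0], pts[:, 1], pts[:, 2]]
    dom = np.argwhere(domain.data > 0)
    out = np.zeros(seeds.shape, dtype=np.int32)
    if len(dom) == 0:
        return out
    # (n_seeds, n_domain) squared distances in mm^2
    d2 = (((pts[:, None, :] - dom[None, :, :]) * sp) ** 2).sum(axis=2)
    dmin = d2.min(axis=0)
    tied = d2 <= dmin[None, :] + 1e-6
    winner = np.where(tied, labs[:, None], np.iinfo(np.int32).max).min(axis=0)
    out[dom[:, 0], dom[:, 1], dom[:, 2]] = winner
    return out
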