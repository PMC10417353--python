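"""Shared fixtures: phantoms at several scales and a once-trained tiny U-Net.

Everything is generated programmatically and seeded; the expensive
session-scoped fixtures (the phantom bank and the trained network) are
built once and shared by the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import gliotrack as gt
from gliotrack.model import TrainConfig, UnetConfig, build_unet3d, train


@pytest.fixture(scope="session")
def default_case() -> gt.PhantomCase:
    """The default 64^3 @ 2 mm phantom."""
    return gt.generate_phantom(gt.PhantomSpec())


@pytest.fixture(scope="session")
def mm1_case() -> gt.PhantomCase:
    """A clinical-resolution (1 mm isotropic), low-noise phantom."""
    spec = gt.PhantomSpec(grid_shape=(96, 96, 96), spacing_mm=(1, 1, 1), noise_sd=0.02, seed=4)
    return gt.generate_phantom(spec)


def random_phantom_specs(
    n: int,
    seed: int,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> list[gt.PhantomSpec]:
    """Varied lesion geometries on a small grid (training diversity)."""
    rng = np.random.default_rng(seed)
    specs = []
    center0 = (np.asarray(grid_shape, float) - 1) / 2
    for i in range(n):
        cav = rng.uniform(7, 12)
        rim = rng.uniform(2, 4)
        nod = rng.uniform(0, 4)
        ede = max(rng.uniform(16, 24), cav + rim + 2 * nod + 1)
        center = center0 + rng.uniform(-2.5, 2.5, 3) / np.asarray(spacing_mm) * 4.0
        specs.append(
            gt.PhantomSpec(
                grid_shape=grid_shape,
                spacing_mm=spacing_mm,
                seed=seed + i,
                cavity_center=tuple(center),
                cavity_radius_mm=cav,
                rim_thickness_mm=rim,
                edema_radius_mm=ede,
                nodule_radius_mm=nod,
                noise_sd=0.05,
            )
        )
    return specs


@pytest.fixture(scope="session")
def phantom_bank() -> list[tuple[gt.ChannelStack, gt.PhantomCase]]:
    """14 varied 32^3 phantoms with their GTV1 input stacks."""
    out = []
    for spec in random_phantom_specs(14, seed=7):
        case = gt.generate_phantom(spec)
        stack = gt.standardize_case(case.ce_t1w, case.flair, case.brain_mask, "GTV1")
        out.append((stack, case))
    return out


@pytest.fixture(scope="session")
def trained_gtv1(phantom_bank):
    """A small GTV1 U-Net trained on 10 phantoms, validated on 4.

    Deliberately desk-scale (32^3 volumes, base_filters 8) so the whole
    session stays within a CPU-minutes budget; shared by the segmentation-
    recovery acceptance test and the inference-consistency tests.
    """
    pairs = [(stack, case.gtv1_true) for stack, case in phantom_bank]
    train_pairs, val_pairs = pairs[:10], pairs[10:]
    net = build_unet3d(UnetConfig(base_filters=8, depth=3), seed=0)
    cfg = TrainConfig(
        lr=1e-3,
        max_epochs=35,
        crop_shape=(32, 32, 32),
        seed=1,
        early_stop_patience=15,
    )
    net, history = train(net, train_pairs, val_pairs, cfg)
    return net, history, val_pairs
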