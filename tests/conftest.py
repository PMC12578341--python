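"""Shared fixtures: tiny synthetic datasets and desk-scale training runs.

The expensive fixture is ``smoke_runs``: tiny-preset training with two
synthetic stains at 64x64, 200 iterations, three seeds, in both the
paired and unpaired settings.  The trained bundles and held-out error
measurements are shared by the convergence and self-inspection tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from stainforge.networks import ModelBundle, NetworkConfig
from stainforge.synthetic import build_dataset, default_profiles
from stainforge.training import TileDataset, TrainConfig, Trainer, held_out_cycle_error

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")

SMOKE_SEEDS = (0, 1, 2)
SMOKE_ITERATIONS = 200
SMOKE_TILES = 16
SMOKE_TILE_SIZE = 64


@pytest.fixture(scope="session")
def two_stain_profiles():
    profiles = default_profiles()
    return {name: profiles[name] for name in list(profiles)[:2]}


@pytest.fixture(scope="session")
def paired_dataset(tmp_path_factory, two_stain_profiles):
    root = tmp_path_factory.mktemp("ds_paired")
    build_dataset(two_stain_profiles, SMOKE_TILES, "paired", seed=100,
                  out_dir=root / "ds", tile_size=SMOKE_TILE_SIZE)
    return TileDataset(root / "ds")

@pytest.fixture(scope="session")
def unpaired_dataset(tmp_path_factory, two_stain_profiles):
    root = tmp_path_factory.mktemp("ds_unpaired")
    build_dataset(two_stain_profiles, SMOKE_TILES, "unpaired", seed=100,
                  out_dir=root / "ds", tile_size=SMOKE_TILE_SIZE)
    return TileDataset(root / "ds")


@pytest.fixture(scope="session")
def held_out_pairs(tmp_path_factory, two_stain_profiles):
    """Paired held-out tiles (ground truth available regardless of the
    training setting) for reconstruction-error evaluation."""
    root = tmp_path_factory.mktemp("ds_heldout")
    build_dataset(two_stain_profiles, 6, "paired", seed=999,
                  out_dir=root / "ds", tile_size=SMOKE_TILE_SIZE)
    held = TileDataset(root / "ds")
    return {
        stain: [(held.load("HE", k), held.load(stain, k)) for k in held.he_keys]
        for stain in held.stains
    }


def _run_smoke(dataset, setting: str, seed: int, held_out_pairs):
    bundle = ModelBundle.build(dataset.stains, NetworkConfig.tiny(), seed=seed)

    def mean_err(b):
        return float(np.mean([
            held_out_cycle_error(b, s, held_out_pairs[s], dataset.hsv_ranges[s])
            for s in dataset.stains
        ]))

    err_init = mean_err(bundle)
    config = TrainConfig(setting=setting, seed=seed,
                         max_iterations=SMOKE_ITERATIONS, iterations_per_epoch=50)
    trainer = Trainer(bundle, config, dataset.hsv_ranges)
    records = trainer.fit(dataset)
    return {
        "bundle": bundle,
        "records": records,
        "err_init": err_init,
        "err_final": mean_err(bundle),
    }


@pytest.fixture(scope="session")
def smoke_runs(paired_dataset, unpaired_dataset, held_out_pairs):
    """Trained tiny bundles: {(setting, seed): run info}."""
    runs = {}
    for setting, dataset in (("paired", paired_dataset), ("unpaired", unpaired_dataset)):
        for seed in SMOKE_SEEDS:
            runs[(setting, seed)] = _run_smoke(dataset, setting, seed, held_out_pairs)
    return runs
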