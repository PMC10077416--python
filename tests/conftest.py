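import copy

import numpy as np
import pytest

import protonlet as pl


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_grid(values, spacing=(2.0, 2.0, 2.0), quantity="dose_Gy"):
    return pl.VoxelGrid(np.asarray(values, float), spacing, quantity=quantity)


def random_grid(rng, shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0), scale=20.0,
                quantity="dose_Gy"):
    return pl.VoxelGrid(scale * rng.random(shape), spacing, quantity=quantity)


def random_mask(rng, shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0), p=0.4, name="s"):
    m = rng.random(shape) < p
    if not m.any():
        m.flat[0] = True
    return pl.StructureMask(name, m, spacing)


@pytest.fixture
def small_config():
    """Coarse (4 mm) variant of the shipped study for fast pipeline tests."""
    cfg = copy.deepcopy(pl.default_config().raw)
    cfg["grid"] = {"shape": [80, 60, 24], "spacing_mm": [4.0, 4.0, 4.0]}
    cfg["metrics"]["structures"] = ["body", "ctv", "heart", "left_atrium", "lmca"]
    return cfg


@pytest.fixture
def small_phantom(small_config):
    return pl.build_phantom(small_config)


@pytest.fixture(scope="session")
def default_report():
    """The seeded default study (all four beam arrangements, 2 mm grid)."""
    return pl.run_study(pl.default_config())


def metric_value(report, plan, structure, flavour, metric):
    m = report.metrics
    sel = m[(m["plan"] == plan) & (m["structure"] == structure)
            & (m["flavour"] == flavour) & (m["metric"] == metric)]
    assert len(sel) == 1, f"expected one row, got\n{sel}"
    return float(sel["value"].iloc[0])
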