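"""Shared fixtures: small soil columns and a session-scoped synthetic
grid run used by the integration and acceptance tests."""

from __future__ import annotations

import pytest

from peatfire.hydrology import SoilColumn, SoilLayer


def make_layer(**kw) -> SoilLayer:
    defaults = dict(thickness=0.1, bulk_density=0.8, om_fraction=0.3,
                    theta_r=0.05, theta_s=0.45, vg_alpha=3.6, vg_n=1.56, ksat=0.5)
    defaults.update(kw)
    return SoilLayer(**defaults)


def make_column(n_layers=10, thickness=0.1, wtdx=0.5, **layer_kw) -> SoilColumn:
    layers = tuple(make_layer(thickness=thickness, **layer_kw) for _ in range(n_layers))
    return SoilColumn(layers=layers, wtdx=wtdx)


@pytest.fixture
def mineral_layer():
    return make_layer()


@pytest.fixture
def peat_layer():
    return make_layer(bulk_density=0.1, om_fraction=0.9, theta_r=0.10,
                      theta_s=0.88, vg_alpha=4.0, vg_n=1.45, ksat=10.0)


@pytest.fixture(scope="session")
def synthetic_run():
    """One default 50-cell, 8-year synthetic study, shared across tests."""
    from peatfire.pipeline import run_synthetic_study

    return run_synthetic_study(seed=1)
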