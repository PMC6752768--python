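"""Shared fixtures: reference cells, media, fields and random draws."""

import numpy as np
import pytest

from rotospec import (DEFAULT_MEDIUM, DielectricMaterial, DoubleShellCell,
                      FieldConfig, SingleShellCell)


@pytest.fixture
def medium():
    return DEFAULT_MEDIUM


@pytest.fixture
def field():
    return FieldConfig.log_spaced()


@pytest.fixture
def mose_e_cell():
    """Early-stage reference cell (aggregate LM parameter set)."""
    return SingleShellCell(radius=6e-6, membrane_thickness=4e-9,
                           membrane=DielectricMaterial(30.0, 32e-6),
                           cytoplasm=DielectricMaterial(45.0, 0.90))


@pytest.fixture
def mose_l_cell():
    """Late-stage reference cell (aggregate LM parameter set)."""
    return SingleShellCell(radius=6e-6, membrane_thickness=4e-9,
                           membrane=DielectricMaterial(30.0, 52e-6),
                           cytoplasm=DielectricMaterial(45.0, 1.0))


def draw_single_shell(rng: np.random.Generator) -> SingleShellCell:
    """One random single-shell cell inside the physiological fit bounds."""
    return SingleShellCell(
        radius=rng.uniform(3e-6, 10e-6),
        membrane_thickness=rng.uniform(4e-9, 40e-9),
        membrane=DielectricMaterial(rng.uniform(1.0, 30.0),
                                    10 ** rng.uniform(-12, -3)),
        cytoplasm=DielectricMaterial(rng.uniform(45.0, 125.0),
                                     rng.uniform(0.01, 2.0)))


def draw_double_shell(rng: np.random.Generator) -> DoubleShellCell:
    radius = rng.uniform(3e-6, 10e-6)
    t = rng.uniform(4e-9, 40e-9)
    r_n = rng.uniform(0.3, 0.8) * (radius - t)
    return DoubleShellCell(
        radius=radius, membrane_thickness=t,
        membrane=DielectricMaterial(rng.uniform(1.0, 30.0),
                                    10 ** rng.uniform(-12, -3)),
        cytoplasm=DielectricMaterial(rng.uniform(45.0, 125.0),
                                     rng.uniform(0.01, 2.0)),
        nucleus_radius=r_n,
        nuclear_envelope_thickness=rng.uniform(20e-9, min(80e-9, 0.5 * r_n)),
        nuclear_envelope=DielectricMaterial(rng.uniform(1.0, 100.0),
                                            10 ** rng.uniform(-5, -1)),
        nucleoplasm=DielectricMaterial(rng.uniform(45.0, 125.0),
                                       rng.uniform(0.01, 2.0)))
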