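import numpy as np
import pytest

from marrowflow.geometry import (
    MARGIN,
    PORE,
    SOLID,
    GeometrySpec,
    VoxelDomain,
    generate_trabecular,
)
from marrowflow.materials import MaterialSpec, material_for_group
from marrowflow.waveforms import LoadSpec


@pytest.fixture(scope="session")
def mat_con() -> MaterialSpec:
    return material_for_group("CON")


@pytest.fixture(scope="session")
def load_default() -> LoadSpec:
    return LoadSpec()


@pytest.fixture(scope="session")
def small_domain() -> VoxelDomain:
    """16^3 trabecular core at BV/TV 0.30 used by the cheaper solver tests."""
    return generate_trabecular(GeometrySpec(grid_n=16, bvtv_target=0.30, seed=2))


def make_block_domain(n: int = 8, margin: int = 2, pitch: float = 18.0) -> VoxelDomain:
    """Fully solid n^3 core inside a fluid margin shell."""
    full = n + 2 * margin
    lab = np.full((full,) * 3, MARGIN, dtype=np.int8)
    core = tuple(slice(margin, margin + n) for _ in range(3))
    lab[core] = SOLID
    return VoxelDomain(labels=lab, pitch=pitch, margin_vox=margin)


def make_empty_core_domain(n: int = 8, margin: int = 2) -> VoxelDomain:
    full = n + 2 * margin
    lab = np.full((full,) * 3, MARGIN, dtype=np.int8)
    core = tuple(slice(margin, margin + n) for _ in range(3))
    lab[core] = PORE
    return VoxelDomain(labels=lab, pitch=18.0, margin_vox=margin)


@pytest.fixture(scope="session")
def cycle_small(small_domain, mat_con, load_default):
    """One fast-path loading cycle on the small geometry (shared)."""
    from marrowflow.driver import run_cycle

    return run_cycle(small_domain, mat_con, load_default, n_steps=20)
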