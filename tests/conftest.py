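import numpy as np
import pytest

import lesym
from lesym.simulate import (
    EffectParams,
    LesionEffect,
    LLParams,
    SimulationConfig,
    TractSpec,
    WMLFieldParams,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small but fully featured scenario: two tracts, planted effects."""
    return lesym.replicate_config(seed=7, n_patients=60, grid_shape=(16, 16, 8))


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    """(atlas, cohort, covariates, subtests, truth) for the tiny scenario."""
    return lesym.simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def replicate_bundle():
    """One replicate of the documented default recovery scenario."""
    cfg = lesym.replicate_config(seed=11)
    return cfg, lesym.simulate_cohort(cfg)


def make_cohort(wml: np.ndarray, ll: np.ndarray | None = None,
                voxel_size=(2.0, 2.0, 2.0)) -> lesym.LesionCohort:
    """Hand-built cohort from stacked binary arrays (n, x, y, z)."""
    wml = np.asarray(wml, dtype=np.uint8)
    if ll is None:
        ll = np.zeros_like(wml)
    n = wml.shape[0]
    grid = lesym.VoxelGrid(shape=wml.shape[1:], voxel_size_mm=voxel_size)
    ids = tuple(f"S{i:03d}" for i in range(n))
    return lesym.LesionCohort(grid=grid, patient_ids=ids,
                              maps={"wml": wml, "ll": np.asarray(ll, dtype=np.uint8)})


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Brute-force BFS connected components; returns the partition as a
    list of frozensets of voxel coordinates (independent oracle)."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    mask = np.asarray(mask, dtype=bool)
    todo = {tuple(c) for c in np.argwhere(mask)}
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            x, y, z = frontier.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return comps


def bh_oracle(p: np.ndarray, q: float) -> np.ndarray:
    """Brute-force Benjamini–Hochberg scan; returns a boolean reject mask."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    if k:
        reject[p <= p[order[k - 1]]] = True
    return reject
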