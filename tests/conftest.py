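"""Shared fixtures: toy structures, scalar test potentials, numeric gradients."""

from __future__ import annotations

import numpy as np
import pytest

from memfold.dynamics import TotalPotential
from memfold.fixtures import make_toy_hairpin
from memfold.model_io import beads_from_conformation


@pytest.fixture(scope="session")
def hairpin():
    """Default 45-residue membrane-spanning helical hairpin + topology."""
    return make_toy_hairpin()


@pytest.fixture(scope="session")
def hairpin_model(hairpin):
    conf, topo = hairpin
    return TotalPotential(topo, boost_range=(1, 19))


@pytest.fixture(scope="session")
def hairpin_native_beads(hairpin):
    conf, topo = hairpin
    return beads_from_conformation(conf, topo.sequence)


@pytest.fixture()
def perturbed_beads(hairpin, hairpin_native_beads):
    """Native hairpin beads jittered by 0.4 Å (fixed seed)."""
    rng = np.random.default_rng(3)
    return hairpin_native_beads + 0.4 * rng.standard_normal(hairpin_native_beads.shape)


def central_difference_forces(energy_fn, coords: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Independent numeric gradient oracle: -dE/dx by central differences."""
    f = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            xp = coords.copy()
            xp[i, d] += h
            xm = coords.copy()
            xm[i, d] -= h
            f[i, d] = -(energy_fn(xp) - energy_fn(xm)) / (2.0 * h)
    return f


class ScalarModel:
    """Duck-typed potential over a single bead, for integrator tests.

    energy(x) takes a (1, 3) array and returns kcal/mol; the gradient is
    supplied analytically.
    """

    def __init__(self, energy, gradient):
        self._energy = energy
        self._gradient = gradient

    def forces(self, coords, bias=None):
        return -self._gradient(coords)

    def energy_terms(self, coords, bias=None):
        v = float(self._energy(coords))
        return {"v_total": v, "v_unbiased": v, "v_bias": 0.0,
                "d": 0.0, "z": float(coords[0, 2]),
                "z_term_a": 0.0, "z_term_b": 0.0}


@pytest.fixture()
def harmonic_1d_model():
    """V = (k/2) x^2 on the x-coordinate of one bead, k = 1 kcal/mol/Å²."""
    k = 1.0

    def energy(c):
        return 0.5 * k * c[0, 0] ** 2

    def grad(c):
        g = np.zeros_like(c)
        g[0, 0] = k * c[0, 0]
        return g

    return ScalarModel(energy, grad), k


@pytest.fixture()
def double_well_1d_model():
    """V = h ((x/w)^2 - 1)^2 on one bead; barrier h = 2 kcal/mol, minima ±w."""
    h, w = 2.0, 2.0

    def energy(c):
        return h * ((c[0, 0] / w) ** 2 - 1.0) ** 2

    def grad(c):
        g = np.zeros_like(c)
        g[0, 0] = h * 2.0 * ((c[0, 0] / w) ** 2 - 1.0) * 2.0 * c[0, 0] / w**2
        return g

    return ScalarModel(energy, grad), h, w
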