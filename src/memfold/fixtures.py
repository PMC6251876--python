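"""Synthetic structures, analytic ensembles, and toy grids with known truth.

Everything here is generated in memory from a spec and a seed — ideal
α-helices with textbook geometry, a Leu-rich helical-hairpin miniprotein that
spans the membrane slab, exactly-Boltzmann umbrella ensembles from analytic
1D/2D potentials for validating the reweighting stack, and hand-built
free-energy grids for validating the path search.  Ground truths travel with
the outputs as metadata so tests never re-derive them ad hoc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import BiasSpec
from .landscape import FreeEnergyGrid, SampleSet
from .model_io import (
    Conformation,
    NativeTopology,
    SBMParams,
    build_native_topology,
)

#: ideal α-helix geometry: rise per residue, backbone helix radius, turn angle
HELIX_RISE = 1.5        # Å per residue
HELIX_RADIUS = 2.3      # Å
HELIX_TURN_DEG = 100.0  # degrees per residue
CB_OFFSET = 1.5         # Å, Cβ placed radially outward from Cα

#: reduced-unit analysis temperature (k_B * T = 1 kcal/mol) for analytic toys
REDUCED_T = 1.0 / 0.0019872041


@dataclass
class ToySpec:
    """Geometry spec for synthetic helices."""

    n_residues: int = 20
    sequence: str | None = None      # default poly-Leu
    z_offset: float = 0.0            # Å, translation of the helix center
    tilt_deg: float = 0.0            # rotation of the axis away from z
    xy_offset: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length mismatch")


def _helix_coords(n: int, phase: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Cα and outward-radial Cβ coordinates of a vertical ideal helix.

    Centered on the z-axis, z spanning symmetrically around 0.
    """
    turn = np.deg2rad(HELIX_TURN_DEG)
    k = np.arange(n)
    ang = phase + k * turn
    z = (k - (n - 1) / 2.0) * HELIX_RISE
    ca = np.column_stack([HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), z])
    cb = np.column_stack([
        (HELIX_RADIUS + CB_OFFSET) * np.cos(ang),
        (HELIX_RADIUS + CB_OFFSET) * np.sin(ang),
        z,
    ])
    return ca, cb


def make_ideal_helix(spec: ToySpec) -> tuple[Conformation, str]:
    """Cα/Cβ trace of an ideal α-helix, vertical by default."""
    seq = spec.sequence or "L" * spec.n_residues
    ca, cb = _helix_coords(spec.n_residues)
    tilt = np.deg2rad(spec.tilt_deg)
    rot = np.array(
        [[np.cos(tilt), 0.0, np.sin(tilt)], [0.0, 1.0, 0.0], [-np.sin(tilt), 0.0, np.cos(tilt)]]
    )
    ca = ca @ rot.T
    cb = cb @ rot.T
    shift = np.array([spec.xy_offset[0], spec.xy_offset[1], spec.z_offset])
    ca += shift
    cb += shift
    cb_out = np.where(
        np.array([aa == "G" for aa in seq])[:, None], np.nan, cb
    )
    conf = Conformation(
        residue_ids=np.arange(1, spec.n_residues + 1), ca_xyz=ca, cb_xyz=cb_out
    )
    return conf, seq


def make_toy_hairpin(
    n_helix: int = 19,
    n_loop: int = 7,
    axis_separation: float = 10.0,
    params: SBMParams | None = None,
) -> tuple[Conformation, NativeTopology]:
    """Membrane-spanning helical hairpin: two antiparallel TM helices + loop.

    Leu-rich transmembrane helices packed at ~10 Å axis separation, joined by
    a polar glycine/asparagine loop arcing over the top interface.  The
    default 45-residue construct has well over 20 native contacts and is
    sized so a full umbrella + replica-exchange + MBAR smoke test runs in
    minutes on one CPU.
    """
    n = 2 * n_helix + n_loop
    ca1, cb1 = _helix_coords(n_helix)
    ca2, cb2 = _helix_coords(n_helix, phase=np.pi)
    # helix B runs antiparallel (downwards), displaced along x
    flip = np.diag([1.0, -1.0, -1.0])
    ca2 = ca2 @ flip
    cb2 = cb2 @ flip
    ca2[:, 0] += axis_separation
    cb2[:, 0] += axis_separation

    # loop: arc in the xz-plane over the top of the two helices
    top1 = ca1[-1]
    top2 = ca2[0]
    t = np.linspace(0.0, np.pi, n_loop + 2)[1:-1]
    mid = 0.5 * (top1 + top2)
    half = 0.5 * np.linalg.norm(top2 - top1)
    arc_height = 4.5
    axis_dir = (top2 - top1) / (2.0 * half)
    ca_loop = np.array([
        mid - axis_dir * half * np.cos(ti) + np.array([0.0, 0.0, arc_height * np.sin(ti)])
        for ti in t
    ])

    ca = np.vstack([ca1, ca_loop, ca2])
    seq = "L" * n_helix + ("GNGSNG" + "G" * max(0, n_loop - 6))[:n_loop] + "L" * n_helix
    cb = np.full((n, 3), np.nan)
    cb[:n_helix] = cb1
    cb[n_helix + n_loop:] = cb2
    for i in range(n_helix, n_helix + n_loop):
        if seq[i] != "G":
            d = ca[i] - mid
            d[2] = 0.0
            nrm = np.linalg.norm(d)
            u = d / nrm if nrm > 1e-9 else np.array([0.0, 1.0, 0.0])
            cb[i] = ca[i] + CB_OFFSET * u + np.array([0.0, 0.0, CB_OFFSET])

    conf = Conformation(residue_ids=np.arange(1, n + 1), ca_xyz=ca, cb_xyz=cb)
    ss = "H" * n_helix + "C" * n_loop + "H" * n_helix
    helices = [(1, n_helix), (n_helix + n_loop + 1, n)]
    topo = build_native_topology(conf, seq, helices, ss, params or SBMParams())
    return conf, topo


# ---------------------------------------------------------------------------
# analytic umbrella ensembles (exact Boltzmann samples, known free energy)


def _grid_sample(x: np.ndarray, logp: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw samples from a 1-D density tabulated on a fine grid (inverse CDF)."""
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    u = rng.random(n)
    idx = np.searchsorted(cdf, u)
    # jitter within a grid cell to avoid discretization artifacts
    dx = x[1] - x[0]
    return x[np.clip(idx, 0, len(x) - 1)] + (rng.random(n) - 0.5) * dx


def make_analytic_umbrella_ensemble(
    potential,
    window_centers: np.ndarray,
    k_bias: float = 2.0,
    n_per_window: int = 2000,
    seed: int = 0,
    x_grid: np.ndarray | None = None,
) -> SampleSet:
    """Exact-Boltzmann umbrella ensemble from a declared 1-D potential.

    ``potential`` maps x (Å-like units) to energy in kT; window biases are
    U_bias = k_bias*(x - c)^2 (no 1/2), also in kT.  The true free-energy
    curve F(x) = U(x) (up to a constant) is attached as ground truth.
    """
    rng = np.random.default_rng(seed)
    centers = np.asarray(window_centers, dtype=float)
    if x_grid is None:
        lo = centers.min() - 4.0
        hi = centers.max() + 4.0
        x_grid = np.linspace(lo, hi, 4001)
    u0 = np.asarray(potential(x_grid), dtype=float)

    xs = []
    for c in centers:
        logp = -(u0 + k_bias * (x_grid - c) ** 2)
        xs.append(_grid_sample(x_grid, logp, n_per_window, rng))
    x_all = np.concatenate(xs)

    import pandas as pd

    frames = pd.DataFrame({
        "d": x_all,
        "z": np.zeros_like(x_all),
        "z_term_a": np.zeros_like(x_all),
        "z_term_b": np.zeros_like(x_all),
        "v_unbiased": np.asarray(potential(x_all), dtype=float),  # kT units
        "v_boost_region": np.zeros_like(x_all),
    })
    k_states = len(centers)
    u_kn = np.empty((k_states, len(x_all)))
    for k, c in enumerate(centers):
        u_kn[k] = frames["v_unbiased"].to_numpy() + k_bias * (x_all - c) ** 2
    states = [
        (BiasSpec(d_center=c, k_d=k_bias, k_z=0.0, z_tether_center=0.0), REDUCED_T)
        for c in centers
    ]
    return SampleSet(
        frames=frames,
        u_kn=u_kn,
        n_samples=np.full(k_states, n_per_window),
        states=states,
        metadata={
            "true_potential": potential,
            "x_grid": x_grid,
            "k_bias": k_bias,
            "reduced_temperature": REDUCED_T,
        },
    )


def quartic_double_well(height: float, center: float = 0.0, half_width: float = 1.0):
    """U(x) = height * ((x-c)^2/w^2 - 1)^2: minima at c±w, barrier = height (kT)."""

    def u(x):
        s = ((np.asarray(x, dtype=float) - center) / half_width) ** 2
        return height * (s - 1.0) ** 2

    return u


def double_well_delta_f(potential, x_grid: np.ndarray, split: float) -> float:
    """True free-energy difference F(right) - F(left) of a 1-D double well, kT."""
    u = np.asarray(potential(x_grid), dtype=float)
    left = x_grid <= split
    from scipy.special import logsumexp

    f_left = -logsumexp(-u[left])
    f_right = -logsumexp(-u[~left])
    return float(f_right - f_left)


def make_two_basin_landscape_ensemble(
    barrier: float = 4.0,
    d_minima: tuple[float, float] = (40.0, 90.0),
    z_levels: tuple[float, float] = (0.0, -15.0),
    kappa_z: float = 0.5,
    window_centers: np.ndarray | None = None,
    k_bias: float = 0.05,
    n_per_window: int = 1500,
    seed: int = 0,
) -> SampleSet:
    """2D two-basin landscape sampled with umbrella windows along D.

    The potential (kT units) is a quartic double well in D with the stated
    barrier, plus a harmonic channel in Z whose center slides from
    z_levels[0] in the compact basin to z_levels[1] in the extended basin —
    emulating an inserted-folded basin and an interface-unfolded basin.  The
    minimum-path profile has an exactly known barrier (the quartic height),
    attached as ground truth.
    """
    rng = np.random.default_rng(seed)
    d_a, d_b = d_minima
    c = 0.5 * (d_a + d_b)
    w = 0.5 * (d_b - d_a)
    u_d = quartic_double_well(barrier, center=c, half_width=w)

    # the z-channel slides between its two levels on the extended-basin flank,
    # away from the saddle, so the binned saddle free energy stays sharp
    z_shift = c + 0.6 * w

    def z_center(d):
        return z_levels[0] + (z_levels[1] - z_levels[0]) / (
            1.0 + np.exp(-(np.asarray(d, dtype=float) - z_shift) / (0.1 * w))
        )

    if window_centers is None:
        window_centers = np.arange(d_a - 10.0, d_b + 10.0 + 1e-9, 5.0)
    centers = np.asarray(window_centers, dtype=float)
    x_grid = np.linspace(d_a - 20.0, d_b + 20.0, 6001)
    u0 = u_d(x_grid)

    ds, zs = [], []
    for ctr in centers:
        logp = -(u0 + k_bias * (x_grid - ctr) ** 2)
        d_samp = _grid_sample(x_grid, logp, n_per_window, rng)
        z_samp = z_center(d_samp) + rng.standard_normal(n_per_window) / np.sqrt(2.0 * kappa_z)
        ds.append(d_samp)
        zs.append(z_samp)
    d_all = np.concatenate(ds)
    z_all = np.concatenate(zs)

    import pandas as pd

    v_unbiased = u_d(d_all) + kappa_z * (z_all - z_center(d_all)) ** 2
    frames = pd.DataFrame({
        "d": d_all,
        "z": z_all,
        "z_term_a": np.zeros_like(d_all),
        "z_term_b": np.zeros_like(d_all),
        "v_unbiased": v_unbiased,
        "v_boost_region": np.zeros_like(d_all),
    })
    k_states = len(centers)
    u_kn = np.empty((k_states, len(d_all)))
    for k, ctr in enumerate(centers):
        u_kn[k] = v_unbiased + k_bias * (d_all - ctr) ** 2
    states = [
        (BiasSpec(d_center=ctr, k_d=k_bias, k_z=0.0, z_tether_center=0.0), REDUCED_T)
        for ctr in centers
    ]
    return SampleSet(
        frames=frames,
        u_kn=u_kn,
        n_samples=np.full(k_states, n_per_window),
        states=states,
        metadata={
            "true_barrier_kt": barrier,
            "d_minima": d_minima,
            "z_levels": z_levels,
            "reduced_temperature": REDUCED_T,
            "path_potential": u_d,
        },
    )


# ---------------------------------------------------------------------------
# toy free-energy grids


def make_toy_grid(
    shape: tuple[int, int],
    wall_col: int | None = None,
    gap_row: int | None = None,
    wells: list[tuple[int, int, float]] | None = None,
    base_f: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> FreeEnergyGrid:
    """Hand-built free-energy grid with optional wall, gap, and wells.

    Unit bins; a wall column is unoccupied except at the gap row; wells
    subtract depth at the stated bins.  The result is re-zeroed to min F = 0.
    """
    n_d, n_z = shape
    if n_d < 2 or n_z < 2:
        raise ValueError("grid must be at least 2x2")
    rng = np.random.default_rng(seed)
    f = np.full((n_d, n_z), float(base_f))
    if noise > 0:
        f += noise * rng.random((n_d, n_z))
    occupied = np.ones((n_d, n_z), dtype=bool)
    if wall_col is not None:
        occupied[wall_col, :] = False
        if gap_row is not None:
            occupied[wall_col, gap_row] = True
    for (i, j, depth) in wells or []:
        f[i, j] -= depth
    f[~occupied] = np.inf
    f -= f[occupied].min()
    return FreeEnergyGrid(
        d_edges=np.arange(n_d + 1, dtype=float),
        z_edges=np.arange(n_z + 1, dtype=float),
        f=f,
        occupied=occupied,
    )


def make_random_grid(shape: tuple[int, int], seed: int, f_scale: float = 3.0) -> FreeEnergyGrid:
    """Fully occupied grid with uniform-random free energies, re-zeroed."""
    rng = np.random.default_rng(seed)
    f = f_scale * rng.random(shape)
    f -= f.min()
    return FreeEnergyGrid(
        d_edges=np.arange(shape[0] + 1, dtype=float),
        z_edges=np.arange(shape[1] + 1, dtype=float),
        f=f,
        occupied=np.ones(shape, dtype=bool),
    )
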