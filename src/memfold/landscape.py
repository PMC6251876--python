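"""Free-energy landscapes over (D, Z) and minimum-free-energy paths.

D is the end-to-end distance between the terminal Cα beads (the observable of
the force-spectroscopy experiments being modeled); Z is the mean Cα
z-coordinate, measuring membrane insertion depth.  Frames pooled across
umbrella windows and temperatures are reweighted with MBAR to any target
state — including perturbed states with uniformly strengthened contacts in a
residue window, or with a pulling tilt -k_force*D — then binned into a 2D
free-energy grid in units of kT.  Low-free-energy pathways across the grid
are found with Dijkstra's algorithm on the 8-connected bin lattice with node
weights e^F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import K_B, PN_ANGSTROM_TO_KCAL_MOL
from .dynamics import BiasSpec, TotalPotential, Trajectory
from .mbar import MBAR
from .model_io import Conformation, NativeTopology, beads_from_conformation


@dataclass
class OrderParams:
    """Scalar observables of one frame, Å (fractions for q)."""

    d: float
    z: float
    q: float
    d_tm56: float
    z_tm56: float


def _tm56_range(topo: NativeTopology) -> tuple[int, int] | None:
    if len(topo.tm_helices) < 2:
        return None
    ordered = sorted(topo.tm_helices)
    return ordered[-2][0], ordered[-1][1]


def compute_order_params(
    conf: Conformation,
    topo: NativeTopology,
    q_tol: float = 1.0,
    q_min_sep: int = 3,
) -> OrderParams:
    """D, Z, native-contact fraction Q, and the TM5-6 hairpin variants.

    Q is the fraction of Cα-Cα pairwise distances (residue separation >=
    q_min_sep) within q_tol of their native value.  The hairpin variants
    restrict D and Z to the last two transmembrane helices.
    """
    ca = conf.ca_xyz
    native_ca = topo.native_conformation().ca_xyz
    d = float(np.linalg.norm(ca[-1] - ca[0]))
    z = float(ca[:, 2].mean())

    n = len(ca)
    ii, jj = np.triu_indices(n, k=q_min_sep)
    dist = np.linalg.norm(ca[jj] - ca[ii], axis=1)
    dist0 = np.linalg.norm(native_ca[jj] - native_ca[ii], axis=1)
    q = float(np.mean(np.abs(dist - dist0) <= q_tol)) if len(ii) else 1.0

    rng56 = _tm56_range(topo)
    if rng56 is not None:
        idx = topo.helix_residue_indices(*rng56)
        sub = ca[idx]
        d56 = float(np.linalg.norm(sub[-1] - sub[0]))
        z56 = float(sub[:, 2].mean())
    else:
        d56 = d
        z56 = z
    return OrderParams(d=d, z=z, q=q, d_tm56=d56, z_tm56=z56)


# ---------------------------------------------------------------------------
# sample pooling and reweighting


@dataclass
class PerturbationSpec:
    """Target-state definition for reweighting.

    contact_boost_factor scales the contact energies of pairs whose residues
    both fall in boosted_range (the normalization is NOT recomputed — the
    perturbation acts on the stored energies); k_force tilts the landscape by
    -k_force*D toward extended states.
    """

    contact_boost_factor: float = 1.0
    boosted_range: tuple[int, int] | None = None
    k_force: float = 0.0   # kcal/mol/Å

    def __post_init__(self) -> None:
        if self.contact_boost_factor <= 0:
            raise ValueError("boost factor must be > 0")


@dataclass
class SampleSet:
    """Pooled frames with reduced energies in every sampling state.

    frames holds the per-frame observables and raw energy components
    (v_unbiased, v_boost_region, d, z, terminal z's); u_kn is (K, N); states
    records each sampling state's bias and temperature.
    """

    frames: pd.DataFrame
    u_kn: np.ndarray
    n_samples: np.ndarray
    states: list[tuple[BiasSpec, float]]
    coords: np.ndarray | None = None      # optional (N, n_beads, 3)
    equilibration_fraction: float = 0.75
    stride: int = 1
    metadata: dict = field(default_factory=dict)
    _mbar: MBAR | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def mbar(self) -> MBAR:
        if self._mbar is None:
            self._mbar = MBAR(self.u_kn, self.n_samples)
        return self._mbar


def _bias_energy_columns(df: pd.DataFrame, bias: BiasSpec) -> np.ndarray:
    s = bias.spring_scale
    u = s * bias.k_d * (df["d"].to_numpy() - bias.d_center) ** 2
    u = u + s * bias.k_z * (df["z_term_a"].to_numpy() - bias.z_tether_center) ** 2
    u = u + s * bias.k_z * (df["z_term_b"].to_numpy() - bias.z_tether_center) ** 2
    u = u - bias.k_force * df["d"].to_numpy()
    return u


def build_sample_set(
    runs: list[tuple[BiasSpec, float, Trajectory]],
    equilibration_fraction: float = 0.75,
    stride: int = 1,
    keep_coords: bool = False,
) -> SampleSet:
    """Pool umbrella/replica trajectories into an MBAR-ready sample set.

    The leading ``equilibration_fraction`` of each trajectory is discarded
    (the production analysis uses the final quarter of each run) and the rest
    subsampled by ``stride``.
    """
    states = [(bias, temp) for bias, temp, _ in runs]
    chunks, coord_chunks, counts = [], [], []
    for bias, temp, traj in runs:
        df = traj.energies
        first = int(np.floor(equilibration_fraction * len(df)))
        sel = df.iloc[first::stride].reset_index(drop=True)
        chunks.append(sel)
        counts.append(len(sel))
        if keep_coords:
            coord_chunks.append(traj.coords[first::stride])
    frames = pd.concat(chunks, ignore_index=True)
    v0 = frames["v_unbiased"].to_numpy()
    u_kn = np.empty((len(states), len(frames)))
    for k, (bias, temp) in enumerate(states):
        u_kn[k] = (v0 + _bias_energy_columns(frames, bias)) / (K_B * temp)
    return SampleSet(
        frames=frames,
        u_kn=u_kn,
        n_samples=np.asarray(counts),
        states=states,
        coords=np.concatenate(coord_chunks) if keep_coords and coord_chunks else None,
        equilibration_fraction=equilibration_fraction,
        stride=stride,
    )


def perturbed_reduced_energy(
    frames: pd.DataFrame, pert: PerturbationSpec, temperature: float
) -> np.ndarray:
    """Reduced energy of every pooled frame in a perturbed unbiased state.

    u = [V_unbiased + (boost-1)*V_contacts(boosted window) - k_force*D] / kT.
    """
    u = frames["v_unbiased"].to_numpy().astype(float).copy()
    if pert.contact_boost_factor != 1.0:
        if "v_boost_region" not in frames.columns:
            raise ValueError(
                "contact boost requested but the frames carry no v_boost_region "
                "column; re-run the simulation with boost_range bookkeeping enabled"
            )
        u += (pert.contact_boost_factor - 1.0) * frames["v_boost_region"].to_numpy()
    if pert.k_force != 0.0:
        u -= pert.k_force * frames["d"].to_numpy()
    return u / (K_B * temperature)


def mbar_weights(
    samples: SampleSet, pert: PerturbationSpec, temperature: float
) -> np.ndarray:
    """Normalized per-frame weights of the perturbed target state."""
    u_target = perturbed_reduced_energy(samples.frames, pert, temperature)
    return samples.mbar().weights(u_target)


# ---------------------------------------------------------------------------
# free-energy grids


@dataclass
class FreeEnergyGrid:
    """Binned 2D free-energy surface F(D, Z) in kT, minimum at 0."""

    d_edges: np.ndarray
    z_edges: np.ndarray
    f: np.ndarray          # (n_d, n_z); +inf in unoccupied bins
    occupied: np.ndarray   # bool mask

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def locate(self, d: float, z: float) -> tuple[int, int]:
        i = int(np.clip(np.searchsorted(self.d_edges, d, side="right") - 1, 0, len(self.d_edges) - 2))
        j = int(np.clip(np.searchsorted(self.z_edges, z, side="right") - 1, 0, len(self.z_edges) - 2))
        return i, j

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.occupied)
        return pd.DataFrame(
            {"d": self.d_centers[ii], "z": self.z_centers[jj], "f_kt": self.f[ii, jj]}
        )


def free_energy_grid(
    d: np.ndarray,
    z: np.ndarray,
    weights: np.ndarray,
    d_bin: float = 2.0,
    z_bin: float = 0.5,
    d_range: tuple[float, float] | None = None,
    z_range: tuple[float, float] | None = None,
) -> FreeEnergyGrid:
    """F(bin) = -ln(sum of frame weights in the bin), shifted so min F = 0.

    Empty bins are masked as unreachable rather than capped.
    """
    d = np.asarray(d, dtype=float)
    z = np.asarray(z, dtype=float)
    weights = np.asarray(weights, dtype=float)
    d_lo, d_hi = d_range if d_range else (d.min(), d.max())
    z_lo, z_hi = z_range if z_range else (z.min(), z.max())
    d_edges = np.arange(d_lo, d_hi + d_bin, d_bin)
    z_edges = np.arange(z_lo, z_hi + z_bin, z_bin)
    if len(d_edges) < 2 or len(z_edges) < 2:
        raise ValueError("degenerate grid: all frames fall in one bin")
    w, _, _ = np.histogram2d(d, z, bins=[d_edges, z_edges], weights=weights)
    occupied = w > 0
    f = np.full_like(w, np.inf)
    f[occupied] = -np.log(w[occupied])
    f -= f[occupied].min()
    return FreeEnergyGrid(d_edges=d_edges, z_edges=z_edges, f=f, occupied=occupied)


def sample_set_grid(
    samples: SampleSet,
    pert: PerturbationSpec,
    temperature: float = 373.0,
    **binning,
) -> FreeEnergyGrid:
    """Convenience: MBAR weights for a target state, then the (D, Z) grid."""
    w = mbar_weights(samples, pert, temperature)
    return free_energy_grid(
        samples.frames["d"].to_numpy(), samples.frames["z"].to_numpy(), w, **binning
    )


# ---------------------------------------------------------------------------
# minimum-free-energy paths


@dataclass
class LandscapePath:
    """Ordered 8-connected bin path across a free-energy grid."""

    nodes: list[tuple[int, int]]
    d: np.ndarray
    z: np.ndarray
    f: np.ndarray
    cost: float


def _grid_graph(grid: FreeEnergyGrid) -> nx.Graph:
    g = nx.Graph()
    n_d, n_z = grid.f.shape
    # F is already relative to the grid minimum, keeping e^F in range
    w_node = np.where(grid.occupied, np.exp(np.where(grid.occupied, grid.f, 0.0)), np.inf)
    for i in range(n_d):
        for j in range(n_z):
            if not grid.occupied[i, j]:
                continue
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < n_d and 0 <= b < n_z and grid.occupied[a, b]:
                        g.add_edge(
                            (i, j), (a, b),
                            weight=0.5 * (w_node[i, j] + w_node[a, b]),
                        )
            g.add_node((i, j))
    return g


def dijkstra_path(
    grid: FreeEnergyGrid, start: tuple[float, float], end: tuple[float, float]
) -> LandscapePath:
    """Minimum-cost path between two (D, Z) points on the occupied lattice.

    Node weights are e^F; edge weights average the two node weights; each bin
    connects to its eight nearest neighbors.
    """
    s = grid.locate(*start)
    e = grid.locate(*end)
    for name, node in (("start", s), ("end", e)):
        if not grid.occupied[node]:
            raise ValueError(f"{name} point {node} maps to an unoccupied bin")
    if s == e:
        return LandscapePath(
            nodes=[s],
            d=np.array([grid.d_centers[s[0]]]),
            z=np.array([grid.z_centers[s[1]]]),
            f=np.array([grid.f[s]]),
            cost=0.0,
        )
    g = _grid_graph(grid)
    try:
        cost, nodes = nx.single_source_dijkstra(g, s, e, weight="weight")
    except nx.NetworkXNoPath:
        raise ValueError("no path: start and end lie in disconnected regions") from None
    ii = np.array([n[0] for n in nodes])
    jj = np.array([n[1] for n in nodes])
    return LandscapePath(
        nodes=nodes,
        d=grid.d_centers[ii],
        z=grid.z_centers[jj],
        f=grid.f[ii, jj],
        cost=float(cost),
    )


def path_profile(path: LandscapePath) -> pd.DataFrame:
    """1-D free-energy profile along a path, reported against each node's D."""
    return pd.DataFrame({"d": path.d, "z": path.z, "f_kt": path.f})


def path_barrier(profile: pd.DataFrame) -> dict[str, float]:
    """Barrier bookkeeping along a 1-D profile: peak minus flanking minima."""
    f = profile["f_kt"].to_numpy()
    if len(f) < 2:
        return {"barrier_forward": 0.0, "barrier_reverse": 0.0, "peak_f": float(f.max(initial=0.0))}
    peak = int(np.argmax(f))
    before = f[: peak + 1].min()
    after = f[peak:].min()
    return {
        "barrier_forward": float(f[peak] - before),
        "barrier_reverse": float(f[peak] - after),
        "peak_f": float(f[peak]),
    }


# ---------------------------------------------------------------------------
# representative structures


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body fit of one Cα set onto another.

    Returns the transformed coordinates and the RMSD after fitting.
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    fitted = rot.apply(mob_c) + reference.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return fitted, rmsd


def select_representatives(
    samples: SampleSet,
    topo: NativeTopology,
    d_range: tuple[float, float],
    z_range: tuple[float, float],
    n: int = 3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """The n lowest-energy frames in a (D, Z) box, superposed on Cα.

    Requires the sample set to carry coordinates (keep_coords=True when
    pooling).  Returns the selected frame records (energy-sorted) and the
    superposed flat bead coordinate stack.
    """
    if samples.coords is None:
        raise ValueError("sample set has no coordinates; pool with keep_coords=True")
    df = samples.frames
    mask = (
        (df["d"] >= d_range[0]) & (df["d"] <= d_range[1])
        & (df["z"] >= z_range[0]) & (df["z"] <= z_range[1])
    )
    idx = np.nonzero(mask.to_numpy())[0]
    if len(idx) == 0:
        raise ValueError("no frames in the requested (D, Z) region")
    if len(idx) < n:
        raise ValueError(f"only {len(idx)} frames in region, {n} requested")
    order = idx[np.argsort(df["v_unbiased"].to_numpy()[idx])][:n]
    selected = df.iloc[order].reset_index(drop=True)
    coords = samples.coords[order].copy()
    is_ca = ~topo.bead_is_cb
    ref_ca = coords[0][is_ca]
    for k in range(1, n):
        mob = coords[k]
        mob_ca = mob[is_ca]
        mob_center = mob_ca.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_ca - ref_ca.mean(axis=0), mob_ca - mob_center)
        coords[k] = rot.apply(mob - mob_center) + ref_ca.mean(axis=0)
    return selected, coords


# ---------------------------------------------------------------------------
# force bookkeeping


def force_tilt_kT(force_pn: float, delta_x: float, temperature: float) -> float:
    """Free-energy tilt (kT) between two states differing in extension.

    A force change of f pN shifts the relative free energy of states whose
    end-to-end distances differ by delta_x Å by f*delta_x/kT.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if force_pn < 0 or delta_x < 0:
        raise ValueError("force and extension change must be >= 0")
    return force_pn * delta_x * PN_ANGSTROM_TO_KCAL_MOL / (K_B * temperature)


def rate_limiting_extension_change(dx_from_folded: float, dx_from_unfolded: float) -> float:
    """End-to-end distance change of a two-sided transition.

    The distances from the folded and unfolded basins to the transition state
    add up to the total extension change of the rate-limiting step.
    """
    return float(dx_from_folded) + float(dx_from_unfolded)
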