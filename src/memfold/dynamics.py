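"""Langevin sampling of the combined protein + bilayer potential.

Supports harmonic umbrella biases on the end-to-end distance D with z-tethers
on the termini, a constant pulling term -k_force*D, and temperature replica
exchange over a ladder of temperatures.  Integration is BAOAB with uniform
bead masses; energies are kcal/mol, lengths Å, time fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bilayer import BilayerParams, HelixAssignment, bilayer_forces, burial_energy, helix_assignment, helix_pair_energy, orientation_energy
from .constants import DEFAULT_TEMPERATURE_LADDER, K_B, KCAL_MOL_TO_DA_A2_FS2
from .forcefield import BackboneFF, amh_go_energy, amh_go_forces, amh_go_restricted_energy
from .model_io import NativeTopology


@dataclass
class SimulationConfig:
    """Integrator and schedule settings."""

    timestep: float = 5.0            # fs
    damping_time: float = 10000.0    # fs
    n_steps: int = 100_000
    save_every: int = 4000
    temperature_ladder: tuple = DEFAULT_TEMPERATURE_LADDER
    rng_seed: int = 0
    bead_mass: float = 110.0         # Da
    blowup_energy: float = 1e6       # kcal/mol

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")
        ladder = np.asarray(self.temperature_ladder)
        if len(ladder) > 1 and not np.all(np.diff(ladder) > 0):
            raise ValueError("temperature ladder must be strictly increasing")


@dataclass
class BiasSpec:
    """Umbrella bias on D plus z-tethers on the termini plus a pulling tilt.

    The harmonic convention is U = k (xi - xi0)^2 without the 1/2 factor;
    ``half_factor`` switches to the k/2 convention and is recorded in output
    metadata because a silent factor of two would distort the reweighting.
    """

    d_center: float = 0.0
    k_d: float = 0.02                # kcal/mol/Å²
    z_tether_center: float = -17.0   # Å
    k_z: float = 0.1                 # kcal/mol/Å²
    k_force: float = 0.0             # kcal/mol/Å
    half_factor: bool = False

    def __post_init__(self) -> None:
        if self.k_d < 0 or self.k_z < 0:
            raise ValueError("spring constants must be >= 0")

    @property
    def spring_scale(self) -> float:
        return 0.5 if self.half_factor else 1.0


def make_umbrella_schedule(
    ranges: list[tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Umbrella centers from (start, stop, step) ranges, inclusive ends.

    The default follows the production schedule: 40-112 Å every 2 Å plus
    118-340 Å every 6 Å (75 centers).
    """
    if ranges is None:
        ranges = [(40.0, 112.0, 2.0), (118.0, 340.0, 6.0)]
    centers: list[float] = []
    for start, stop, step in ranges:
        if step <= 0:
            raise ValueError("increment must be positive")
        n = int(round((stop - start) / step))
        centers.extend(start + step * k for k in range(n + 1) if start + step * k <= stop + 1e-9)
    return np.unique(np.asarray(centers))


# ---------------------------------------------------------------------------
# total potential


@dataclass
class TotalPotential:
    """V_total = V_SBM + V_bilayer (+ umbrella/tether/pulling bias).

    Bundles the topology with backbone and bilayer parameter sets and exposes
    energy breakdowns and forces on the flat bead array.
    """

    topo: NativeTopology
    backbone: BackboneFF = None
    bilayer_params: BilayerParams = None
    helices: HelixAssignment = None
    include_bilayer: bool = True
    boost_range: tuple[int, int] | None = None   # residue-id window for bookkeeping

    def __post_init__(self) -> None:
        if self.backbone is None:
            self.backbone = BackboneFF(self.topo)
        if self.bilayer_params is None:
            self.bilayer_params = BilayerParams()
        if self.helices is None:
            self.helices = helix_assignment(self.topo)

    @property
    def termini_beads(self) -> tuple[int, int]:
        ca = np.nonzero(~self.topo.bead_is_cb)[0]
        return int(ca[0]), int(ca[-1])

    def end_to_end(self, coords: np.ndarray) -> float:
        a, b = self.termini_beads
        return float(np.linalg.norm(coords[b] - coords[a]))

    def mean_ca_z(self, coords: np.ndarray) -> float:
        return float(coords[~self.topo.bead_is_cb, 2].mean())

    def energy_terms(self, coords: np.ndarray, bias: BiasSpec | None = None) -> dict[str, float]:
        terms = {"v_amh_go": amh_go_energy(coords, self.topo)}
        terms.update(self.backbone.energy_terms(coords))
        if self.include_bilayer:
            terms["v_burial"] = burial_energy(coords, self.topo.sequence, self.bilayer_params, self.topo)
            terms["v_orientation"] = orientation_energy(coords, self.helices, self.bilayer_params, self.topo)
            terms["v_helix_pair"] = helix_pair_energy(coords, self.helices, self.bilayer_params, self.topo)
        else:
            terms["v_burial"] = terms["v_orientation"] = terms["v_helix_pair"] = 0.0
        if self.boost_range is not None:
            terms["v_boost_region"] = amh_go_restricted_energy(coords, self.topo, self.boost_range)
        terms["d"] = self.end_to_end(coords)
        terms["z"] = self.mean_ca_z(coords)
        a, b = self.termini_beads
        terms["z_term_a"] = float(coords[a, 2])
        terms["z_term_b"] = float(coords[b, 2])
        terms["v_unbiased"] = (
            terms["v_amh_go"] + terms["v_con"] + terms["v_chain"] + terms["v_chi"]
            + terms["v_rama"] + terms["v_excl"]
            + terms["v_burial"] + terms["v_orientation"] + terms["v_helix_pair"]
        )
        if bias is not None:
            terms["v_bias"] = self.bias_energy(coords, bias)
            terms["v_total"] = terms["v_unbiased"] + terms["v_bias"]
        else:
            terms["v_bias"] = 0.0
            terms["v_total"] = terms["v_unbiased"]
        return terms

    def bias_energy(self, coords: np.ndarray, bias: BiasSpec) -> float:
        a, b = self.termini_beads
        d = self.end_to_end(coords)
        s = bias.spring_scale
        u = s * bias.k_d * (d - bias.d_center) ** 2
        u += s * bias.k_z * (coords[a, 2] - bias.z_tether_center) ** 2
        u += s * bias.k_z * (coords[b, 2] - bias.z_tether_center) ** 2
        u -= bias.k_force * d
        return float(u)

    def forces(self, coords: np.ndarray, bias: BiasSpec | None = None) -> np.ndarray:
        f = amh_go_forces(coords, self.topo) + self.backbone.forces(coords)
        if self.include_bilayer:
            f += bilayer_forces(coords, self.topo, self.helices, self.bilayer_params)
        if bias is not None:
            f += self.bias_forces(coords, bias)
        return f

    def bias_forces(self, coords: np.ndarray, bias: BiasSpec) -> np.ndarray:
        f = np.zeros_like(coords)
        a, b = self.termini_beads
        dvec = coords[b] - coords[a]
        d = max(float(np.linalg.norm(dvec)), 1e-12)
        unit = dvec / d
        s = bias.spring_scale
        g = 2.0 * s * bias.k_d * (d - bias.d_center) - bias.k_force
        f[b] -= g * unit
        f[a] += g * unit
        f[a, 2] -= 2.0 * s * bias.k_z * (coords[a, 2] - bias.z_tether_center)
        f[b, 2] -= 2.0 * s * bias.k_z * (coords[b, 2] - bias.z_tether_center)
        return f


def umbrella_bias_energy(
    model: TotalPotential, coords: np.ndarray, bias: BiasSpec
) -> float:
    """Bias energy of one conformation (harmonic + tethers + pulling tilt)."""
    return model.bias_energy(coords, bias)


# ---------------------------------------------------------------------------
# Langevin integration


@dataclass
class Trajectory:
    """Saved frames (flat bead coordinates) plus the per-frame energy table."""

    coords: np.ndarray               # (n_frames, n_beads, 3)
    energies: pd.DataFrame
    final_coords: np.ndarray = None
    final_velocities: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.coords)


class IntegrationBlowupError(RuntimeError):
    pass


def langevin_run(
    coords0: np.ndarray,
    model: TotalPotential,
    config: SimulationConfig,
    temperature: float,
    bias: BiasSpec | None = None,
    rng: np.random.Generator | None = None,
    velocities0: np.ndarray | None = None,
) -> Trajectory:
    """BAOAB Langevin dynamics at one temperature.

    Deterministic given (seed, config); frames and the energy breakdown are
    saved every ``save_every`` steps.  Raises IntegrationBlowupError naming
    the step if the potential energy diverges.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    x = np.array(coords0, dtype=float)
    n_beads = len(x)
    m = config.bead_mass
    dt = config.timestep
    gamma = 1.0 / config.damping_time
    kt = K_B * temperature * KCAL_MOL_TO_DA_A2_FS2   # Da Å²/fs²
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kt / m * (1.0 - c1 * c1))

    v = np.zeros_like(x) if velocities0 is None else np.array(velocities0, dtype=float)
    f = model.forces(x, bias) * KCAL_MOL_TO_DA_A2_FS2   # Da Å/fs²

    frames, rows = [], []

    def record(step: int) -> None:
        terms = model.energy_terms(x, bias)
        if not np.isfinite(terms["v_total"]) or abs(terms["v_total"]) > config.blowup_energy:
            raise IntegrationBlowupError(
                f"potential energy diverged at step {step}: {terms['v_total']:.3g} kcal/mol"
            )
        terms["step"] = step
        rows.append(terms)
        frames.append(x.copy())

    for step in range(1, config.n_steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal((n_beads, 3))
        x += 0.5 * dt * v
        f = model.forces(x, bias) * KCAL_MOL_TO_DA_A2_FS2
        v += 0.5 * dt * f / m
        if step % config.save_every == 0:
            record(step)

    return Trajectory(
        coords=np.array(frames) if frames else np.zeros((0, n_beads, 3)),
        energies=pd.DataFrame(rows),
        final_coords=x,
        final_velocities=v,
        metadata={
            "temperature": temperature,
            "seed": config.rng_seed,
            "harmonic_half_factor": bool(bias.half_factor) if bias else None,
            "timestep_fs": dt,
            "damping_time_fs": config.damping_time,
        },
    )


# ---------------------------------------------------------------------------
# temperature replica exchange


@dataclass
class ReplicaExchangeResult:
    trajectories: list[Trajectory]          # one per temperature rung
    swap_attempts: np.ndarray               # per adjacent pair
    swap_accepts: np.ndarray

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.swap_attempts > 0, self.swap_accepts / self.swap_attempts, np.nan
            )


def replica_exchange(
    coords0: np.ndarray,
    model: TotalPotential,
    config: SimulationConfig,
    bias: BiasSpec | None = None,
    ladder: tuple | None = None,
    swap_every: int = 4000,
    seed: int | None = None,
) -> ReplicaExchangeResult:
    """Temperature replica exchange with adjacent-pair Metropolis swaps.

    All rungs share one umbrella bias.  Swap proposals alternate between the
    even and odd adjacent pairs; configurations (not temperatures) are
    exchanged with probability min(1, exp[(beta_i - beta_j)(E_i - E_j)]).
    """
    ladder = tuple(ladder if ladder is not None else config.temperature_ladder)
    n_rep = len(ladder)
    seed = config.rng_seed if seed is None else seed
    master = np.random.default_rng(seed)
    replica_rngs = [np.random.default_rng(s) for s in master.integers(0, 2**31 - 1, n_rep)]
    swap_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))

    xs = [np.array(coords0, dtype=float) for _ in range(n_rep)]
    vs = [None] * n_rep
    segments: list[list[Trajectory]] = [[] for _ in range(n_rep)]
    attempts = np.zeros(n_rep - 1, dtype=int)
    accepts = np.zeros(n_rep - 1, dtype=int)

    n_rounds = config.n_steps // swap_every
    seg_config_kwargs = dict(
        timestep=config.timestep, damping_time=config.damping_time,
        n_steps=swap_every, save_every=config.save_every,
        bead_mass=config.bead_mass, blowup_energy=config.blowup_energy,
    )
    for rnd in range(n_rounds):
        for k in range(n_rep):
            seg = langevin_run(
                xs[k], model, SimulationConfig(rng_seed=seed, **seg_config_kwargs),
                ladder[k], bias, rng=replica_rngs[k], velocities0=vs[k],
            )
            segments[k].append(seg)
            xs[k] = seg.final_coords
            vs[k] = seg.final_velocities
        start = rnd % 2   # alternate (even, odd) adjacent pairs
        energies = [model.energy_terms(xs[k], bias)["v_total"] for k in range(n_rep)]
        for i in range(start, n_rep - 1, 2):
            attempts[i] += 1
            beta_i = 1.0 / (K_B * ladder[i])
            beta_j = 1.0 / (K_B * ladder[i + 1])
            log_acc = (beta_i - beta_j) * (energies[i] - energies[i + 1])
            if log_acc >= 0 or swap_rng.random() < np.exp(log_acc):
                accepts[i] += 1
                xs[i], xs[i + 1] = xs[i + 1], xs[i]
                vs[i], vs[i + 1] = vs[i + 1], vs[i]
                energies[i], energies[i + 1] = energies[i + 1], energies[i]

    trajectories = []
    for k in range(n_rep):
        coords = np.concatenate([s.coords for s in segments[k]]) if segments[k] else np.zeros((0, len(coords0), 3))
        frames = pd.concat([s.energies for s in segments[k]], ignore_index=True) if segments[k] else pd.DataFrame()
        if len(frames):
            frames["step"] = np.arange(1, len(frames) + 1) * config.save_every
        trajectories.append(
            Trajectory(
                coords=coords, energies=frames, final_coords=xs[k],
                final_velocities=vs[k],
                metadata={"temperature": ladder[k], "seed": seed},
            )
        )
    return ReplicaExchangeResult(
        trajectories=trajectories, swap_attempts=attempts, swap_accepts=accepts
    )
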