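"""Implicit lipid-bilayer potential: burial + helix orientation + helix pair.

The membrane is a slab normal to z, centered at z = 0, with interfaces near
z = ±15 Å.  Every term is modulated by a smooth tanh switching envelope that
is ~1 deep inside the slab and decays to 0 outside, so the bilayer's influence
turns on and off continuously as beads cross the interfaces.  The burial term
is a per-residue transfer free energy (water-octanol scale); the orientation
term penalizes the cylindrical radius of gyration of each transmembrane helix,
aligning inserted helices with the membrane normal; the helix-pair term is a
lipid-mediated interaction between helix centers of mass fit to simulations of
cylindrical inclusions in a DMPC bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import load_burial_scale
from .model_io import Conformation, NativeTopology, beads_from_conformation

#: quintic fit to the lipid-mediated pair potential (kcal/mol, r in Å),
#: highest power first
HELIX_PAIR_COEFFS = (
    -3.7673e-6, 6.0103e-4, -3.4889e-2, 8.9378e-1, -9.4119, 26.745,
)


@dataclass
class BilayerParams:
    """Constants of the implicit-membrane terms (kcal/mol, Å)."""

    k_m: float = 0.2                 # switching steepness, 1/Å
    z_m_burial: float = 15.0
    z_m_orientation: float = 12.0
    z_m_helix_pair: float = 15.0
    k_burial: float = 1.0
    k_orientation: float = 0.1       # kcal/mol/Å²
    k_helix_pair: float = 0.5        # kcal/mol
    f_coefficients: tuple = HELIX_PAIR_COEFFS
    f_cutoff: float = 30.0           # polynomial valid up to here
    f_taper: float = 2.0             # linear switch to zero over this width
    burial_scale: dict[str, float] = field(default_factory=load_burial_scale)

    def __post_init__(self) -> None:
        if self.k_m <= 0:
            raise ValueError("k_m must be > 0")
        for name in ("z_m_burial", "z_m_orientation", "z_m_helix_pair"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class HelixAssignment:
    """Cα bead indices of each transmembrane helix (equal masses)."""

    helices: list[np.ndarray]   # each entry: Cα bead indices of one helix

    def __post_init__(self) -> None:
        for h in self.helices:
            if len(h) < 2:
                raise ValueError("a helix needs at least 2 residues")


def helix_assignment(topo: NativeTopology) -> HelixAssignment:
    """Map the topology's TM helix ranges onto Cα bead indices."""
    bead_res = topo.bead_residue
    is_ca = ~topo.bead_is_cb
    helices = []
    for first, last in topo.tm_helices:
        res_idx = topo.helix_residue_indices(first, last)
        beads = np.nonzero(is_ca & np.isin(bead_res, res_idx))[0]
        helices.append(beads)
    return HelixAssignment(helices=helices)


# ---------------------------------------------------------------------------
# switching


def switching_theta(z, z_m: float, k_m: float = 0.2):
    """Smooth membrane envelope: ~1 for |z| << z_m, 0.5 at |z| = z_m, -> 0 outside."""
    z = np.asarray(z, dtype=float)
    return 0.5 * np.tanh(k_m * (z + z_m)) + 0.5 * np.tanh(k_m * (z_m - z))


def _switching_dtheta_dz(z, z_m: float, k_m: float):
    z = np.asarray(z, dtype=float)
    return 0.5 * k_m * (
        1.0 / np.cosh(k_m * (z + z_m)) ** 2 - 1.0 / np.cosh(k_m * (z_m - z)) ** 2
    )


# ---------------------------------------------------------------------------
# burial


def burial_energy(
    conf: Conformation | np.ndarray,
    sequence: str,
    params: BilayerParams | None = None,
    topo: NativeTopology | None = None,
) -> float:
    """Sequence-dependent membrane burial: sum_i A(aa_i) * Theta(z_i).

    Applied at the Cα z-coordinate of every residue; hydrophobic residues
    (negative A) are stabilized inside the slab.
    """
    params = params or BilayerParams()
    z = _ca_z(conf, sequence, topo)
    a_vals = _residue_scale(sequence, params)
    theta = switching_theta(z, params.z_m_burial, params.k_m)
    return float(params.k_burial * np.sum(a_vals * theta))


def _residue_scale(sequence: str, params: BilayerParams) -> np.ndarray:
    try:
        return np.array([params.burial_scale[aa] for aa in sequence])
    except KeyError as err:
        raise ValueError(f"no burial scale entry for residue {err.args[0]!r}") from None


def _ca_z(conf, sequence: str, topo: NativeTopology | None) -> np.ndarray:
    if isinstance(conf, Conformation):
        return conf.ca_xyz[:, 2]
    coords = np.asarray(conf, dtype=float)
    if topo is None:
        raise ValueError("bead arrays require the topology for the Cα layout")
    return coords[~topo.bead_is_cb, 2]


# ---------------------------------------------------------------------------
# orientation


def _helix_rg2(ca: np.ndarray, z_m: float, k_m: float) -> float:
    """Switched cylindrical radius-of-gyration squared of one helix."""
    r = np.sqrt(ca[:, 0] ** 2 + ca[:, 1] ** 2)
    com = ca.mean(axis=0)
    r_cm = np.hypot(com[0], com[1])
    theta = switching_theta(ca[:, 2], z_m, k_m)
    return float(np.sum((r - r_cm) ** 2 * theta) / len(ca))


def orientation_energy(
    conf: Conformation | np.ndarray,
    helices: HelixAssignment,
    params: BilayerParams | None = None,
    topo: NativeTopology | None = None,
) -> float:
    """k_orientation * sum over helices of the cylindrical Rg^2.

    Zero for a straight helix standing along z (all radial coordinates equal
    to the center-of-mass radius); grows as a membrane-resident helix tilts.
    """
    params = params or BilayerParams()
    coords = _full_coords(conf, topo)
    total = 0.0
    for beads in helices.helices:
        total += _helix_rg2(coords[beads], params.z_m_orientation, params.k_m)
    return float(params.k_orientation * total)


def _full_coords(conf, topo: NativeTopology | None) -> np.ndarray:
    if isinstance(conf, Conformation):
        if topo is None:
            raise ValueError("Conformation input requires the topology")
        return beads_from_conformation(conf, topo.sequence)
    return np.asarray(conf, dtype=float)


# ---------------------------------------------------------------------------
# helix pair


def helix_pair_f(r, params: BilayerParams | None = None):
    """Lipid-mediated pair potential f(r) between two helix centers of mass.

    The quintic is evaluated up to f_cutoff and ramped linearly to zero over
    the taper width beyond it; 0 at larger separations.
    """
    params = params or BilayerParams()
    r = np.asarray(r, dtype=float)
    poly = np.polyval(params.f_coefficients, np.minimum(r, params.f_cutoff))
    ramp = np.clip((params.f_cutoff + params.f_taper - r) / params.f_taper, 0.0, 1.0)
    return poly * ramp


def _helix_pair_df_dr(r: float, params: BilayerParams) -> float:
    dc = getattr(params, "_f_dcoeffs", None)
    if dc is None:
        dc = np.polyder(np.poly1d(params.f_coefficients)).coeffs
        object.__setattr__(params, "_f_dcoeffs", dc)
    if r <= params.f_cutoff:
        return float(np.polyval(dc, r))
    if r >= params.f_cutoff + params.f_taper:
        return 0.0
    return float(-np.polyval(params.f_coefficients, params.f_cutoff) / params.f_taper)


def helix_pair_energy(
    conf: Conformation | np.ndarray,
    helices: HelixAssignment,
    params: BilayerParams | None = None,
    topo: NativeTopology | None = None,
) -> float:
    """k_helix_pair * sum over helix pairs of f(r_com) * Theta(z_i) * Theta(z_j)."""
    params = params or BilayerParams()
    coords = _full_coords(conf, topo)
    coms = np.array([coords[b].mean(axis=0) for b in helices.helices])
    total = 0.0
    for i in range(len(coms)):
        for j in range(i + 1, len(coms)):
            r = float(np.linalg.norm(coms[i] - coms[j]))
            ti = switching_theta(coms[i, 2], params.z_m_helix_pair, params.k_m)
            tj = switching_theta(coms[j, 2], params.z_m_helix_pair, params.k_m)
            total += float(helix_pair_f(r, params)) * float(ti) * float(tj)
    return float(params.k_helix_pair * total)


# ---------------------------------------------------------------------------
# combined


def bilayer_energy(
    conf: Conformation | np.ndarray,
    sequence: str,
    helices: HelixAssignment,
    params: BilayerParams | None = None,
    topo: NativeTopology | None = None,
) -> dict[str, float]:
    """All three membrane terms plus their sum, kcal/mol."""
    params = params or BilayerParams()
    parts = {
        "v_burial": burial_energy(conf, sequence, params, topo),
        "v_orientation": orientation_energy(conf, helices, params, topo),
        "v_helix_pair": helix_pair_energy(conf, helices, params, topo),
    }
    parts["v_bilayer"] = parts["v_burial"] + parts["v_orientation"] + parts["v_helix_pair"]
    return parts


def bilayer_forces(
    coords: np.ndarray,
    topo: NativeTopology,
    helices: HelixAssignment,
    params: BilayerParams | None = None,
) -> np.ndarray:
    """-grad of the bilayer potential on the flat bead array."""
    params = params or BilayerParams()
    f = np.zeros_like(coords)
    is_ca = ~topo.bead_is_cb
    ca_idx = np.nonzero(is_ca)[0]

    # burial: z-force on Cα beads
    a_vals = _residue_scale(topo.sequence, params)
    z = coords[ca_idx, 2]
    dtheta = _switching_dtheta_dz(z, params.z_m_burial, params.k_m)
    f[ca_idx, 2] -= params.k_burial * a_vals * dtheta

    # orientation
    for beads in helices.helices:
        ca = coords[beads]
        n = len(ca)
        x, y, zz = ca[:, 0], ca[:, 1], ca[:, 2]
        r = np.sqrt(x * x + y * y)
        com = ca.mean(axis=0)
        r_cm = np.hypot(com[0], com[1])
        theta = switching_theta(zz, params.z_m_orientation, params.k_m)
        dev = r - r_cm
        pref = params.k_orientation / n
        r_safe = np.maximum(r, 1e-12)
        # direct r_i dependence
        gx = pref * 2.0 * dev * theta * x / r_safe
        gy = pref * 2.0 * dev * theta * y / r_safe
        # shared r_cm dependence
        s = pref * 2.0 * np.sum(dev * theta)
        if r_cm > 1e-12:
            gx_cm = -s * (com[0] / r_cm) / n
            gy_cm = -s * (com[1] / r_cm) / n
        else:
            gx_cm = gy_cm = 0.0
        gz = pref * dev**2 * _switching_dtheta_dz(zz, params.z_m_orientation, params.k_m)
        f[beads, 0] -= gx + gx_cm
        f[beads, 1] -= gy + gy_cm
        f[beads, 2] -= gz

    # helix pair
    coms = np.array([coords[b].mean(axis=0) for b in helices.helices])
    zs = coms[:, 2] if len(coms) else np.zeros(0)
    thetas = switching_theta(zs, params.z_m_helix_pair, params.k_m)
    dthetas = _switching_dtheta_dz(zs, params.z_m_helix_pair, params.k_m)
    for i in range(len(coms)):
        for j in range(i + 1, len(coms)):
            dvec = coms[j] - coms[i]
            r = float(np.linalg.norm(dvec))
            fr = float(helix_pair_f(r, params))
            dfr = _helix_pair_df_dr(r, params)
            k = params.k_helix_pair
            # radial part
            if r > 1e-12:
                g = k * dfr * thetas[i] * thetas[j] / r
                bi, bj = helices.helices[i], helices.helices[j]
                f[bj] -= g * dvec / len(bj)
                f[bi] += g * dvec / len(bi)
            # switching part (z of each COM)
            gzi = k * fr * dthetas[i] * thetas[j]
            gzj = k * fr * thetas[i] * dthetas[j]
            f[helices.helices[i], 2] -= gzi / len(helices.helices[i])
            f[helices.helices[j], 2] -= gzj / len(helices.helices[j])
    return f
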