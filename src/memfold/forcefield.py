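"""Structure-based (Go-like) protein potential with analytic forces.

The contact term rewards native bead-pair distances with Gaussian wells whose
depths are normalized so that the native-state energy is exactly -4*N*epsilon
for a chain of N residues, independent of how many contacts the fold has.
Around it sit generic backbone terms — harmonic bonds and pseudo-angles at
native geometry, a chirality restraint fixing Cβ handedness, a soft-sphere
excluded volume, and a dihedral bias toward the native pseudo-dihedral for
helix-assigned residues — which keep the chain protein-like and the helices
intact while the tertiary structure folds and unfolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Conformation, NativeTopology, beads_from_conformation


@dataclass
class EnergyBreakdown:
    """Per-term energies in kcal/mol."""

    v_amh_go: float
    v_con: float
    v_chain: float
    v_chi: float
    v_rama: float
    v_excl: float

    @property
    def v_backbone_total(self) -> float:
        return self.v_con + self.v_chain + self.v_chi + self.v_rama + self.v_excl

    @property
    def v_total_sbm(self) -> float:
        return self.v_amh_go + self.v_backbone_total

    def as_dict(self) -> dict[str, float]:
        return {
            "v_amh_go": self.v_amh_go,
            "v_con": self.v_con,
            "v_chain": self.v_chain,
            "v_chi": self.v_chi,
            "v_rama": self.v_rama,
            "v_excl": self.v_excl,
            "v_backbone_total": self.v_backbone_total,
            "v_total_sbm": self.v_total_sbm,
        }


# ---------------------------------------------------------------------------
# AMH-Go contact potential


def normalization_a(topo: NativeTopology) -> float:
    """Contact-count normalization: a = (1/8N) sum_i |sum_j gamma_ij|^p.

    The outer sum runs over all beads (Cα and Cβ); the inner sum collects the
    weights of bead i's native contacts.  Raises if the topology has no
    contacts, since the contact depths divide by a.
    """
    cached = getattr(topo, "_norm_a_cache", None)
    key = (topo.params.p, topo.params.gamma_short, topo.params.gamma_long, topo.n_contacts)
    if cached is not None and cached[0] == key:
        return cached[1]
    p = topo.params.p
    g = np.zeros(topo.n_beads)
    np.add.at(g, topo.contact_i, topo.contact_gamma)
    np.add.at(g, topo.contact_j, topo.contact_gamma)
    a = float(np.sum(np.abs(g) ** p) / (8.0 * topo.n_residues))
    if a <= 0.0:
        raise ValueError("normalization a = 0: topology has an empty contact set")
    object.__setattr__(topo, "_norm_a_cache", (key, a))
    return a


def contact_epsilon(i: int, j: int, r_ij: float, topo: NativeTopology) -> float:
    """Pair energy of beads (i, j) at separation r_ij; 0 for non-contacts."""
    a = normalization_a(topo)
    lo, hi = min(i, j), max(i, j)
    mask = (topo.contact_i == lo) & (topo.contact_j == hi)
    if not mask.any():
        return 0.0
    k = int(np.nonzero(mask)[0][0])
    params = topo.params
    depth = abs(params.epsilon / a) ** (1.0 / params.p) * topo.contact_gamma[k]
    dev = (r_ij - topo.contact_r0[k]) / topo.contact_sigma[k]
    return float(-depth * np.exp(-0.5 * dev * dev))


def _pair_energies(coords: np.ndarray, topo: NativeTopology, a: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-contact epsilon_ij plus the pair vectors/distances for force reuse."""
    params = topo.params
    dvec = coords[topo.contact_j] - coords[topo.contact_i]
    r = np.linalg.norm(dvec, axis=1)
    depth = abs(params.epsilon / a) ** (1.0 / params.p) * topo.contact_gamma
    dev = (r - topo.contact_r0) / topo.contact_sigma
    eps = -depth * np.exp(-0.5 * dev * dev)
    return eps, dvec, r


def amh_go_energy(conf: Conformation | np.ndarray, topo: NativeTopology) -> float:
    """V_AMH-Go = -(1/2) sum_i |E_i|^p with E_i the contact energy of bead i.

    Each contact pair contributes to the energies of both of its beads, which
    is what makes the native value come out at exactly -4*N*epsilon.
    """
    coords = _as_beads(conf, topo)
    a = normalization_a(topo)
    eps, _, _ = _pair_energies(coords, topo, a)
    e_bead = np.zeros(topo.n_beads)
    np.add.at(e_bead, topo.contact_i, eps)
    np.add.at(e_bead, topo.contact_j, eps)
    return float(-0.5 * np.sum(np.abs(e_bead) ** topo.params.p))


def amh_go_forces(coords: np.ndarray, topo: NativeTopology) -> np.ndarray:
    """-grad of the contact term, kcal/mol/Å, shape (n_beads, 3)."""
    a = normalization_a(topo)
    p = topo.params.p
    eps, dvec, r = _pair_energies(coords, topo, a)
    e_bead = np.zeros(topo.n_beads)
    np.add.at(e_bead, topo.contact_i, eps)
    np.add.at(e_bead, topo.contact_j, eps)
    # dV/d eps_k = -(p/2) (|E_i|^{p-1} + |E_j|^{p-1}) since E_i <= 0
    w_bead = np.abs(e_bead) ** (p - 1.0) if p != 1.0 else np.ones(topo.n_beads)
    w_pair = 0.5 * p * (w_bead[topo.contact_i] + w_bead[topo.contact_j])
    # d eps/d r = eps * (-(r - r0)/sigma^2)
    deps_dr = eps * (-(r - topo.contact_r0) / topo.contact_sigma**2)
    scale = w_pair * deps_dr / np.maximum(r, 1e-12)
    fvec = scale[:, None] * dvec  # force on bead j along +dvec is -dV/dr * unit
    forces = np.zeros_like(coords)
    flats = getattr(topo, "_contact_flat3", None)
    if flats is None:
        flats = (_flat3(topo.contact_i), _flat3(topo.contact_j))
        object.__setattr__(topo, "_contact_flat3", flats)
    _scatter_add(forces, flats[1], -fvec)
    _scatter_add(forces, flats[0], fvec)
    return forces


def amh_go_restricted_energy(
    conf: Conformation | np.ndarray,
    topo: NativeTopology,
    residue_range: tuple[int, int],
) -> float:
    """Contact energy restricted to pairs with both residues in a given range.

    This is the partial sum needed to apply a uniform strength boost to a
    residue window by reweighting (pairwise-additive p = 1 reading).
    """
    coords = _as_beads(conf, topo)
    a = normalization_a(topo)
    eps, _, _ = _pair_energies(coords, topo, a)
    rid = topo.residue_ids[topo.bead_residue]
    lo, hi = residue_range
    inside = (rid >= lo) & (rid <= hi)
    both = inside[topo.contact_i] & inside[topo.contact_j]
    return float(np.sum(eps[both]))


def _flat3(idx: np.ndarray) -> np.ndarray:
    """Flattened (idx*3 + component) index array for fast scatter-adds."""
    return (np.asarray(idx, dtype=np.intp)[:, None] * 3 + np.arange(3)).ravel()


def _scatter_add(f: np.ndarray, flat_idx: np.ndarray, vec: np.ndarray) -> None:
    f.ravel()[:] += np.bincount(flat_idx, vec.ravel(), minlength=f.size)


def _as_beads(conf: Conformation | np.ndarray, topo: NativeTopology) -> np.ndarray:
    if isinstance(conf, Conformation):
        if conf.n_residues != topo.n_residues:
            raise ValueError("conformation does not match topology")
        return beads_from_conformation(conf, topo.sequence)
    coords = np.asarray(conf, dtype=float)
    if coords.shape != (topo.n_beads, 3):
        raise ValueError("bead array does not match topology")
    return coords


# ---------------------------------------------------------------------------
# Backbone terms


@dataclass
class BackboneFF:
    """Generic backbone potential referenced to the native geometry.

    Stiffnesses (kcal/mol units; lengths in Å, angles dimensionless via
    cosines) are strong enough that helices stay formed while tertiary
    contacts break, and soft enough for a 5 fs Langevin timestep.
    """

    topo: NativeTopology
    k_bond: float = 100.0        # kcal/mol/Å², Cα-Cα and Cα-Cβ bonds
    k_angle: float = 20.0        # kcal/mol, on cos(theta)
    k_chi: float = 5.0           # kcal/mol, normalized chirality deviation
    k_rama: float = 2.0          # kcal/mol, 1 - cos(phi - phi0)
    k_excl: float = 20.0         # kcal/mol/Å²
    r_excl: float = 4.0          # Å soft-sphere diameter

    # derived reference geometry (filled in __post_init__)
    bond_i: np.ndarray = field(init=False)
    bond_j: np.ndarray = field(init=False)
    bond_r0: np.ndarray = field(init=False)
    ang_idx: np.ndarray = field(init=False)     # (n_ang, 3) bead indices
    ang_cos0: np.ndarray = field(init=False)
    chi_idx: np.ndarray = field(init=False)     # (n_chi, 4): prev, ca, next, cb
    chi_ref: np.ndarray = field(init=False)     # native triple products
    dih_idx: np.ndarray = field(init=False)     # (n_dih, 4) Cα quadruples
    dih_phi0: np.ndarray = field(init=False)
    excl_i: np.ndarray = field(init=False)
    excl_j: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        topo = self.topo
        coords = topo.native_bead_xyz
        bead_res = topo.bead_residue
        is_cb = topo.bead_is_cb
        ca_of = np.full(topo.n_residues, -1, dtype=int)
        cb_of = np.full(topo.n_residues, -1, dtype=int)
        for b in range(topo.n_beads):
            (cb_of if is_cb[b] else ca_of)[bead_res[b]] = b

        bi, bj = [], []
        for i in range(topo.n_residues - 1):
            bi.append(ca_of[i]); bj.append(ca_of[i + 1])
        for i in range(topo.n_residues):
            if cb_of[i] >= 0:
                bi.append(ca_of[i]); bj.append(cb_of[i])
        self.bond_i = np.asarray(bi, dtype=int)
        self.bond_j = np.asarray(bj, dtype=int)
        self.bond_r0 = np.linalg.norm(coords[self.bond_j] - coords[self.bond_i], axis=1)

        ang = [
            (ca_of[i - 1], ca_of[i], ca_of[i + 1])
            for i in range(1, topo.n_residues - 1)
        ]
        self.ang_idx = np.asarray(ang, dtype=int).reshape(-1, 3)
        if len(ang):
            self.ang_cos0 = _angle_cos(coords, self.ang_idx)
        else:
            self.ang_cos0 = np.zeros(0)

        chi = [
            (ca_of[i + 1], ca_of[i], ca_of[i - 1], cb_of[i])
            for i in range(1, topo.n_residues - 1)
            if cb_of[i] >= 0
        ]
        self.chi_idx = np.asarray(chi, dtype=int).reshape(-1, 4)
        if len(chi):
            self.chi_ref = _triple_products(coords, self.chi_idx)
            # collinear native geometry gives a vanishing reference; drop those
            keep = np.abs(self.chi_ref) > 1e-6
            self.chi_idx = self.chi_idx[keep]
            self.chi_ref = self.chi_ref[keep]
        else:
            self.chi_ref = np.zeros(0)

        ss = topo.secondary_structure
        dih = [
            (ca_of[i - 1], ca_of[i], ca_of[i + 1], ca_of[i + 2])
            for i in range(1, topo.n_residues - 2)
            if ss[i] == "H" and ss[i + 1] == "H"
        ]
        self.dih_idx = np.asarray(dih, dtype=int).reshape(-1, 4)
        self.dih_phi0 = (
            _dihedrals(coords, self.dih_idx) if len(dih) else np.zeros(0)
        )

        # nonbonded soft-sphere pairs: residue separation >= s_min, not native contacts
        n = topo.n_beads
        pi, pj = np.triu_indices(n, k=1)
        sep = np.abs(bead_res[pj] - bead_res[pi])
        keep = sep >= topo.params.s_min
        pi, pj = pi[keep], pj[keep]
        contact_keys = set(zip(topo.contact_i.tolist(), topo.contact_j.tolist()))
        mask = np.array(
            [(a, b) not in contact_keys for a, b in zip(pi.tolist(), pj.tolist())],
            dtype=bool,
        ) if len(pi) else np.zeros(0, dtype=bool)
        self.excl_i = pi[mask]
        self.excl_j = pj[mask]

    # -- energies ----------------------------------------------------------

    def energy_terms(self, coords: np.ndarray) -> dict[str, float]:
        return {
            "v_con": self._bond_energy(coords),
            "v_chain": self._angle_energy(coords),
            "v_chi": self._chi_energy(coords),
            "v_rama": self._rama_energy(coords),
            "v_excl": self._excl_energy(coords),
        }

    def _bond_energy(self, coords: np.ndarray) -> float:
        r = np.linalg.norm(coords[self.bond_j] - coords[self.bond_i], axis=1)
        return float(self.k_bond * np.sum((r - self.bond_r0) ** 2))

    def _angle_energy(self, coords: np.ndarray) -> float:
        if not len(self.ang_idx):
            return 0.0
        c = _angle_cos(coords, self.ang_idx)
        return float(self.k_angle * np.sum((c - self.ang_cos0) ** 2))

    def _chi_energy(self, coords: np.ndarray) -> float:
        if not len(self.chi_idx):
            return 0.0
        c = _triple_products(coords, self.chi_idx)
        return float(self.k_chi * np.sum(((c - self.chi_ref) / np.abs(self.chi_ref)) ** 2))

    def _rama_energy(self, coords: np.ndarray) -> float:
        if not len(self.dih_idx):
            return 0.0
        phi = _dihedrals(coords, self.dih_idx)
        return float(self.k_rama * np.sum(1.0 - np.cos(phi - self.dih_phi0)))

    def _excl_energy(self, coords: np.ndarray) -> float:
        if not len(self.excl_i):
            return 0.0
        r = np.linalg.norm(coords[self.excl_j] - coords[self.excl_i], axis=1)
        overlap = np.maximum(self.r_excl - r, 0.0)
        return float(self.k_excl * np.sum(overlap**2))

    # -- forces ------------------------------------------------------------

    def _flat(self, name: str, idx: np.ndarray) -> np.ndarray:
        cache = self.__dict__.setdefault("_flat_cache", {})
        if name not in cache:
            cache[name] = _flat3(idx)
        return cache[name]

    def forces(self, coords: np.ndarray) -> np.ndarray:
        f = np.zeros_like(coords)
        # bonds
        dvec = coords[self.bond_j] - coords[self.bond_i]
        r = np.linalg.norm(dvec, axis=1)
        g = 2.0 * self.k_bond * (r - self.bond_r0) / np.maximum(r, 1e-12)
        fv = g[:, None] * dvec
        _scatter_add(f, self._flat("bond_j", self.bond_j), -fv)
        _scatter_add(f, self._flat("bond_i", self.bond_i), fv)
        # angles (on cos theta)
        if len(self.ang_idx):
            ii, jj, kk = self.ang_idx.T
            u = coords[ii] - coords[jj]
            v = coords[kk] - coords[jj]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            c = np.einsum("ij,ij->i", u, v) / (nu * nv)
            pref = 2.0 * self.k_angle * (c - self.ang_cos0)
            dc_du = (v / nv[:, None] - c[:, None] * u / nu[:, None]) / nu[:, None]
            dc_dv = (u / nu[:, None] - c[:, None] * v / nv[:, None]) / nv[:, None]
            _scatter_add(f, self._flat("ang_i", ii), -pref[:, None] * dc_du)
            _scatter_add(f, self._flat("ang_k", kk), -pref[:, None] * dc_dv)
            _scatter_add(f, self._flat("ang_j", jj), pref[:, None] * (dc_du + dc_dv))
        # chirality
        if len(self.chi_idx):
            nx, ca, pv, cb = self.chi_idx.T
            u = coords[nx] - coords[ca]
            v = coords[pv] - coords[ca]
            w = coords[cb] - coords[ca]
            c = np.einsum("ij,ij->i", _cross(u, v), w)
            pref = 2.0 * self.k_chi * (c - self.chi_ref) / self.chi_ref**2
            dc_du = _cross(v, w)
            dc_dv = _cross(w, u)
            dc_dw = _cross(u, v)
            _scatter_add(f, self._flat("chi_nx", nx), -pref[:, None] * dc_du)
            _scatter_add(f, self._flat("chi_pv", pv), -pref[:, None] * dc_dv)
            _scatter_add(f, self._flat("chi_cb", cb), -pref[:, None] * dc_dw)
            _scatter_add(f, self._flat("chi_ca", ca), pref[:, None] * (dc_du + dc_dv + dc_dw))
        # dihedral bias
        if len(self.dih_idx):
            phi = _dihedrals(coords, self.dih_idx)
            dv_dphi = self.k_rama * np.sin(phi - self.dih_phi0)
            g1, g2, g3, g4 = _dihedral_gradients(coords, self.dih_idx)
            i1, i2, i3, i4 = self.dih_idx.T
            _scatter_add(f, self._flat("dih_1", i1), -dv_dphi[:, None] * g1)
            _scatter_add(f, self._flat("dih_2", i2), -dv_dphi[:, None] * g2)
            _scatter_add(f, self._flat("dih_3", i3), -dv_dphi[:, None] * g3)
            _scatter_add(f, self._flat("dih_4", i4), -dv_dphi[:, None] * g4)
        # excluded volume
        if len(self.excl_i):
            dvec = coords[self.excl_j] - coords[self.excl_i]
            r2 = np.einsum("ij,ij->i", dvec, dvec)
            active = r2 < self.r_excl * self.r_excl
            if active.any():
                dvec = dvec[active]
                r = np.sqrt(r2[active])
                g = -2.0 * self.k_excl * (self.r_excl - r) / np.maximum(r, 1e-12)
                fv = g[:, None] * dvec
                np.add.at(f, self.excl_j[active], -fv)
                np.add.at(f, self.excl_i[active], fv)
        return f


# ---------------------------------------------------------------------------
# geometry helpers


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without numpy.cross's axis-juggling overhead."""
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _angle_cos(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    return np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )


def _triple_products(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    w = coords[idx[:, 3]] - coords[idx[:, 1]]
    return np.einsum("ij,ij->i", _cross(u, v), w)


def _dihedrals(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    m = _cross(b1, b2)
    n = _cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", m, n)
    y = np.einsum("ij,ij->i", _cross(m, n), b2) / np.maximum(b2n, 1e-12)
    return np.arctan2(y, x)


def _dihedral_gradients(coords: np.ndarray, idx: np.ndarray):
    """d(phi)/d(r) for each of the four atoms of each dihedral."""
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    m = _cross(b1, b2)
    n = _cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    m2 = np.einsum("ij,ij->i", m, m)
    n2 = np.einsum("ij,ij->i", n, n)
    g1 = -(b2n / np.maximum(m2, 1e-12))[:, None] * m
    g4 = (b2n / np.maximum(n2, 1e-12))[:, None] * n
    s12 = (np.einsum("ij,ij->i", b1, b2) / np.maximum(b2n**2, 1e-12))[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / np.maximum(b2n**2, 1e-12))[:, None]
    g2 = -g1 - s12 * g1 + s32 * g4
    g3 = -g4 + s12 * g1 - s32 * g4
    return g1, g2, g3, g4


# ---------------------------------------------------------------------------
# combined SBM surface


def sbm_energy(
    conf: Conformation | np.ndarray,
    topo: NativeTopology,
    backbone: BackboneFF | None = None,
) -> EnergyBreakdown:
    """Full structure-based potential, broken down by term."""
    coords = _as_beads(conf, topo)
    backbone = backbone or BackboneFF(topo)
    terms = backbone.energy_terms(coords)
    return EnergyBreakdown(v_amh_go=amh_go_energy(coords, topo), **terms)


def sbm_forces(
    conf: Conformation | np.ndarray,
    topo: NativeTopology,
    backbone: BackboneFF | None = None,
) -> np.ndarray:
    """-grad V_SBM per bead, kcal/mol/Å."""
    coords = _as_beads(conf, topo)
    backbone = backbone or BackboneFF(topo)
    return amh_go_forces(coords, topo) + backbone.forces(coords)
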