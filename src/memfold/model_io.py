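"""Structures, native topologies, and trajectory I/O for the Cα/Cβ bead model.

A chain is represented by one Cα bead per residue plus one Cβ bead per
non-glycine residue.  The native topology carries everything the forcefield
needs: native pair distances, the Gaussian contact set with its per-pair widths
and weights, transmembrane helix ranges, and the secondary-structure string
that drives the helical dihedral bias.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser

from .constants import ONE_TO_THREE, THREE_TO_ONE


@dataclass
class SBMParams:
    """Parameters of the structure-based (Go-like) contact potential.

    epsilon is the per-contact energy scale in kcal/mol, p the nonadditivity
    exponent (p = 1 gives a pairwise-additive model), r_c the native-contact
    cutoff in Å, and gamma_short/gamma_long the sequence-separation dependent
    weights (short: |i-j| < 5, i.e. helical contacts).
    """

    epsilon: float = 0.8
    p: float = 1.0
    r_c: float = 7.0
    gamma_short: float = 1.0
    gamma_long: float = 0.5
    s_min: int = 3  # minimum residue separation for contacts

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.r_c <= 0:
            raise ValueError("r_c must be > 0")


@dataclass
class Conformation:
    """One frame of a chain: per-residue Cα (required) and Cβ (optional) beads.

    ``cb_xyz`` rows are NaN for residues without a Cβ bead (glycine).
    Residue ids follow author numbering (e.g. 91..271 for GlpG).
    """

    residue_ids: np.ndarray
    ca_xyz: np.ndarray
    cb_xyz: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.ca_xyz = np.asarray(self.ca_xyz, dtype=float)
        self.cb_xyz = np.asarray(self.cb_xyz, dtype=float)
        n = len(self.residue_ids)
        if self.ca_xyz.shape != (n, 3) or self.cb_xyz.shape != (n, 3):
            raise ValueError("coordinate arrays must be (n_residues, 3)")
        if not np.all(np.isfinite(self.ca_xyz)):
            raise ValueError("non-finite Cα coordinates")
        if n > 1 and not np.all(np.diff(self.residue_ids) > 0):
            raise ValueError("residue_ids must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def has_cb(self) -> np.ndarray:
        return np.isfinite(self.cb_xyz).all(axis=1)


_LAYOUT_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def bead_layout(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Flat bead ordering for a sequence: per residue, Cα then Cβ (none for G).

    Returns (bead_residue, bead_is_cb): the residue index and bead kind of
    every bead in the flat coordinate array used by the forcefield and
    integrator.
    """
    cached = _LAYOUT_CACHE.get(sequence)
    if cached is not None:
        return cached
    bead_residue, bead_is_cb = [], []
    for i, aa in enumerate(sequence):
        bead_residue.append(i)
        bead_is_cb.append(False)
        if aa != "G":
            bead_residue.append(i)
            bead_is_cb.append(True)
    result = np.asarray(bead_residue, dtype=int), np.asarray(bead_is_cb, dtype=bool)
    _LAYOUT_CACHE[sequence] = result
    return result


def beads_from_conformation(conf: Conformation, sequence: str) -> np.ndarray:
    """Flatten a Conformation into the (n_beads, 3) array of the bead layout."""
    bead_residue, bead_is_cb = bead_layout(sequence)
    coords = np.empty((len(bead_residue), 3))
    coords[~bead_is_cb] = conf.ca_xyz[bead_residue[~bead_is_cb]]
    coords[bead_is_cb] = conf.cb_xyz[bead_residue[bead_is_cb]]
    if not np.all(np.isfinite(coords)):
        raise ValueError("missing Cβ coordinates for a non-glycine residue")
    return coords


def conformation_from_beads(
    coords: np.ndarray, sequence: str, residue_ids: np.ndarray
) -> Conformation:
    """Inverse of :func:`beads_from_conformation`."""
    bead_residue, bead_is_cb = bead_layout(sequence)
    n = len(sequence)
    ca = np.full((n, 3), np.nan)
    cb = np.full((n, 3), np.nan)
    ca[bead_residue[~bead_is_cb]] = coords[~bead_is_cb]
    cb[bead_residue[bead_is_cb]] = coords[bead_is_cb]
    return Conformation(residue_ids=residue_ids, ca_xyz=ca, cb_xyz=cb)


@dataclass
class NativeTopology:
    """Native-structure bookkeeping for the Go-model contact potential.

    Contacts are bead pairs (Cα-Cα, Cα-Cβ, Cβ-Cβ) whose native distance lies
    below r_c and whose residue separation is at least s_min.  Per-pair widths
    follow sigma_ij = |i-j|^0.15 Å and weights gamma are 1.0 for |i-j| < 5,
    0.5 otherwise, so local (helical) contacts dominate nonlocal ones.
    """

    sequence: str
    residue_ids: np.ndarray
    native_bead_xyz: np.ndarray        # (n_beads, 3), bead_layout order
    contact_i: np.ndarray              # bead indices, i < j
    contact_j: np.ndarray
    contact_r0: np.ndarray             # native distances, Å
    contact_gamma: np.ndarray
    contact_sigma: np.ndarray          # Å
    tm_helices: list[tuple[int, int]]  # inclusive author-numbered ranges
    secondary_structure: str
    params: SBMParams = field(default_factory=SBMParams)

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if len(self.sequence) != len(self.residue_ids):
            raise ValueError("sequence and residue_ids length mismatch")
        if len(self.secondary_structure) != len(self.sequence):
            raise ValueError("secondary structure length mismatch")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return len(self.native_bead_xyz)

    @property
    def n_contacts(self) -> int:
        return len(self.contact_i)

    @property
    def bead_residue(self) -> np.ndarray:
        return bead_layout(self.sequence)[0]

    @property
    def bead_is_cb(self) -> np.ndarray:
        return bead_layout(self.sequence)[1]

    def residue_index(self, residue_id: int) -> int:
        idx = np.searchsorted(self.residue_ids, residue_id)
        if idx >= len(self.residue_ids) or self.residue_ids[idx] != residue_id:
            raise KeyError(f"residue id {residue_id} not in topology")
        return int(idx)

    def helix_residue_indices(self, first: int, last: int) -> np.ndarray:
        mask = (self.residue_ids >= first) & (self.residue_ids <= last)
        return np.nonzero(mask)[0]

    def native_conformation(self) -> Conformation:
        return conformation_from_beads(
            self.native_bead_xyz, self.sequence, self.residue_ids
        )


def build_native_topology(
    conf: Conformation,
    sequence: str,
    tm_helices: list[tuple[int, int]],
    secondary_structure: str,
    params: SBMParams | None = None,
) -> NativeTopology:
    """Derive the contact set, widths, and weights from a native structure.

    Raises on overlapping helix ranges; warns (via an empty contact set being
    rejected later by the normalization) if the structure yields no contacts.
    """
    params = params or SBMParams()
    if conf.n_residues != len(sequence):
        raise ValueError("conformation and sequence lengths disagree")
    sorted_h = sorted(tm_helices)
    for (a0, a1), (b0, b1) in zip(sorted_h, sorted_h[1:]):
        if b0 <= a1:
            raise ValueError(f"overlapping helix ranges {(a0, a1)} and {(b0, b1)}")
    for first, last in tm_helices:
        if first < conf.residue_ids[0] or last > conf.residue_ids[-1]:
            raise ValueError(f"helix range {(first, last)} outside residue ids")

    coords = beads_from_conformation(conf, sequence)
    bead_residue, _ = bead_layout(sequence)
    n_beads = len(coords)

    bi, bj = np.triu_indices(n_beads, k=1)
    seq_sep = np.abs(bead_residue[bj] - bead_residue[bi])
    dist = np.linalg.norm(coords[bj] - coords[bi], axis=1)
    keep = (seq_sep >= params.s_min) & (dist < params.r_c)

    ci, cj, sep, r0 = bi[keep], bj[keep], seq_sep[keep], dist[keep]
    gamma = np.where(sep < 5, params.gamma_short, params.gamma_long)
    sigma = sep.astype(float) ** 0.15

    return NativeTopology(
        sequence=sequence,
        residue_ids=conf.residue_ids,
        native_bead_xyz=coords,
        contact_i=ci,
        contact_j=cj,
        contact_r0=r0,
        contact_gamma=gamma,
        contact_sigma=sigma,
        tm_helices=list(tm_helices),
        secondary_structure=secondary_structure,
        params=params,
    )


# ---------------------------------------------------------------------------
# PDB I/O


def load_structure(pdb_text: str, chain_id: str = "A") -> tuple[Conformation, str]:
    """Parse CA/CB ATOM records of one chain into a Conformation + sequence.

    Residues missing a CA raise; unknown residue names raise.  Author residue
    numbering is preserved.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", io.StringIO(pdb_text))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not found")
    chain = model[chain_id]

    residue_ids, seq, ca, cb = [], [], [], []
    for res in chain:
        if res.id[0] != " ":  # skip heteroatoms/water
            continue
        name = res.get_resname().upper()
        if name not in THREE_TO_ONE:
            raise ValueError(f"unknown residue name {name!r}")
        if "CA" not in res:
            raise ValueError(
                f"residue {name} {res.id[1]} lacks a CA atom (incomplete structure)"
            )
        residue_ids.append(res.id[1])
        seq.append(THREE_TO_ONE[name])
        ca.append(res["CA"].get_coord())
        cb.append(res["CB"].get_coord() if "CB" in res else [np.nan] * 3)

    if not residue_ids:
        raise ValueError("no standard residues with CA atoms found")
    conf = Conformation(
        residue_ids=np.asarray(residue_ids),
        ca_xyz=np.asarray(ca, dtype=float),
        cb_xyz=np.asarray(cb, dtype=float),
    )
    return conf, "".join(seq)


def _pdb_atom_line(
    serial: int, atom: str, resname: str, chain: str, resid: int, xyz: np.ndarray
) -> str:
    return (
        f"ATOM  {serial:5d}  {atom:<3s}{resname:>4s} {chain}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           "
        f"{atom[0]}\n"
    )


def write_structure(conf: Conformation, sequence: str, chain_id: str = "A") -> str:
    """Render a Conformation as PDB text (CA and CB records only)."""
    lines, serial = [], 1
    for i, rid in enumerate(conf.residue_ids):
        resname = ONE_TO_THREE[sequence[i]]
        lines.append(_pdb_atom_line(serial, "CA", resname, chain_id, int(rid), conf.ca_xyz[i]))
        serial += 1
        if np.all(np.isfinite(conf.cb_xyz[i])):
            lines.append(_pdb_atom_line(serial, "CB", resname, chain_id, int(rid), conf.cb_xyz[i]))
            serial += 1
    lines.append("TER\n")
    return "".join(lines)


def write_trajectory_pdb(frames: list[Conformation], sequence: str) -> str:
    """Multi-model PDB text for a list of frames sharing one topology."""
    out = []
    for k, frame in enumerate(frames, start=1):
        if frame.n_residues != len(sequence):
            raise ValueError("frame/topology mismatch in trajectory")
        if k > 1 and not np.array_equal(frame.residue_ids, frames[0].residue_ids):
            raise ValueError("frames do not share one topology")
        out.append(f"MODEL     {k:4d}\n")
        out.append(write_structure(frame, sequence))
        out.append("ENDMDL\n")
    out.append("END\n")
    return "".join(out)


def read_trajectory_pdb(pdb_text: str, chain_id: str = "A") -> tuple[list[Conformation], str]:
    """Read a multi-model PDB back into frames (inverse of write_trajectory_pdb)."""
    frames: list[Conformation] = []
    seq = ""
    chunks = pdb_text.split("ENDMDL")
    for chunk in chunks:
        if "ATOM" not in chunk:
            continue
        conf, seq = load_structure(chunk, chain_id)
        frames.append(conf)
    return frames, seq


# ---------------------------------------------------------------------------
# Columnar trajectory format (runtime artifact, lossless)


def save_trajectory_npz(path, frames: list[Conformation], sequence: str) -> None:
    """Lossless columnar trajectory: one stacked array per bead channel."""
    if frames:
        rid0 = frames[0].residue_ids
        for f in frames[1:]:
            if not np.array_equal(f.residue_ids, rid0):
                raise ValueError("frames do not share one topology")
        residue_ids = rid0
    else:
        residue_ids = np.zeros(0, dtype=int)
    np.savez(
        path,
        sequence=np.array(sequence),
        residue_ids=residue_ids,
        ca=np.array([f.ca_xyz for f in frames]),
        cb=np.array([f.cb_xyz for f in frames]),
    )


def load_trajectory_npz(path) -> tuple[list[Conformation], str]:
    data = np.load(path, allow_pickle=False)
    sequence = str(data["sequence"])
    residue_ids = data["residue_ids"]
    frames = [
        Conformation(residue_ids=residue_ids, ca_xyz=ca, cb_xyz=cb)
        for ca, cb in zip(data["ca"], data["cb"])
    ]
    return frames, sequence


def with_coordinates(topo: NativeTopology, coords: np.ndarray) -> Conformation:
    """Conformation view of a flat bead-coordinate array under ``topo``."""
    return conformation_from_beads(coords, topo.sequence, topo.residue_ids)


def rescaled_params(topo: NativeTopology, **updates) -> NativeTopology:
    """Topology with updated SBMParams (contact set is left untouched)."""
    return replace(topo, params=replace(topo.params, **updates))
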