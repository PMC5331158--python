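"""Backbone geometry: PDB parsing, dihedral angles and C-alpha pseudo-angles.

From each chain we extract the N, CA, C backbone coordinates and compute
either the Ramachandran dihedrals (phi, psi) or the C-alpha trace
pseudo-angles: theta, the planar bond angle at a central CA of three
consecutive CA atoms, and tau, the torsion of four consecutive CA atoms.
Angles are reported in degrees at this interface, matching the file formats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

logger = logging.getLogger(__name__)

CA_BREAK_DISTANCE = 4.5  # Angstrom; larger CA-CA gaps flag a chain break

__all__ = [
    "BackboneChain",
    "parse_pdb",
    "dihedral",
    "planar_angle",
    "phi_psi",
    "theta_tau",
    "build_helix",
    "coords_to_pdb",
]


@dataclass
class BackboneChain:
    """Ordered backbone (N, CA, C) coordinates of one chain.

    ``breaks`` holds indices ``i`` such that the CA-CA step from residue ``i``
    to ``i+1`` exceeds the chain-break bound; no angle is computed across it.
    """

    chain_id: str
    residue_numbers: list[int]
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    breaks: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, float)
        self.ca = np.asarray(self.ca, float)
        self.c = np.asarray(self.c, float)
        if not (self.n.shape == self.ca.shape == self.c.shape):
            raise ValueError("backbone coordinate arrays must align")
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        self.breaks = set(np.nonzero(d > CA_BREAK_DISTANCE)[0].tolist())

    def __len__(self) -> int:
        return self.ca.shape[0]

    def _contiguous(self, start: int, stop: int) -> bool:
        """No break on any CA-CA step in residue window [start, stop]."""
        return not any(start <= b < stop for b in self.breaks)


def _get_atom(residue, name):
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        if "A" in atom.disordered_get_id_list():
            atom = atom.disordered_get("A")
        else:
            atom = atom.disordered_get_list()[0]
    altloc = atom.get_altloc()
    if altloc not in (" ", "", "A"):
        return None
    return atom.get_coord()


def parse_pdb(path) -> list[BackboneChain]:
    """Read backbone chains from a PDB file (first model only).

    Residues missing any of N, CA, C are skipped with a logged warning;
    alternate locations keep conformer 'A' or blank.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no model found in {path}")
    chains = []
    for chain in models[0]:
        nums, ncoords, cacoords, ccoords = [], [], [], []
        for res in chain:
            if not is_aa(res, standard=False):
                continue
            coords = [_get_atom(res, nm) for nm in ("N", "CA", "C")]
            if any(c is None for c in coords):
                logger.warning(
                    "skipping residue %s%s in chain %s: incomplete backbone",
                    res.get_resname(), res.get_id()[1], chain.id,
                )
                continue
            nums.append(res.get_id()[1])
            ncoords.append(coords[0])
            cacoords.append(coords[1])
            ccoords.append(coords[2])
        if nums:
            chains.append(
                BackboneChain(chain.id, nums, np.array(ncoords),
                              np.array(cacoords), np.array(ccoords))
            )
    if not chains:
        raise ValueError(f"no backbone atoms found in {path}")
    return chains


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, in (-180, 180].

    IUPAC sign convention: looking down the p2->p3 bond, a clockwise rotation
    of the far bond relative to the near bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate (collinear) points for torsion")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 and math.isclose(abs(ang), 180.0) else ang


def planar_angle(p1, p2, p3) -> float:
    """Bond angle at ``p2`` in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    u, v = p1 - p2, p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise ValueError("coincident points for planar angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def phi_psi(chain: BackboneChain) -> np.ndarray:
    """(residue_index, phi_deg, psi_deg) rows for interior residues.

    phi_i = torsion(C_{i-1}, N_i, CA_i, C_i);
    psi_i = torsion(N_i, CA_i, C_i, N_{i+1}).  Terminal residues and residues
    adjacent to a chain break yield no value.
    """
    if len(chain) < 3:
        raise ValueError("chain too short for phi/psi")
    rows = []
    for i in range(1, len(chain) - 1):
        if not chain._contiguous(i - 1, i + 1):
            continue
        phi = dihedral(chain.c[i - 1], chain.n[i], chain.ca[i], chain.c[i])
        psi = dihedral(chain.n[i], chain.ca[i], chain.c[i], chain.n[i + 1])
        rows.append((chain.residue_numbers[i], phi, psi))
    return np.array(rows, dtype=float).reshape(-1, 3)


def theta_tau(chain: BackboneChain) -> np.ndarray:
    """(residue_index, theta_deg, tau_deg) rows from the CA trace.

    theta_i is the planar angle at CA_i of (CA_{i-1}, CA_i, CA_{i+1});
    tau_i the torsion of (CA_{i-1}, CA_i, CA_{i+1}, CA_{i+2}).  Rows need a
    full unbroken window of four CA atoms.
    """
    if len(chain) < 4:
        raise ValueError("chain too short for theta/tau")
    rows = []
    for i in range(1, len(chain) - 2):
        if not chain._contiguous(i - 1, i + 2):
            continue
        th = planar_angle(chain.ca[i - 1], chain.ca[i], chain.ca[i + 1])
        ta = dihedral(chain.ca[i - 1], chain.ca[i], chain.ca[i + 1],
                      chain.ca[i + 2])
        rows.append((chain.residue_numbers[i], th, ta))
    return np.array(rows, dtype=float).reshape(-1, 3)


# --------------------------------------------------------------------- #
# synthetic backbone construction (test/demonstration geometry)          #
# --------------------------------------------------------------------- #

# idealized backbone covalent geometry (Angstrom / degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}


def _place_atom(a, b, c, length, angle_deg, torsion_deg):
    """Natural-extension-of-reference-frame placement of the next atom."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -length * math.cos(ang),
            length * math.sin(ang) * math.cos(tor),
            length * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_helix(n_res: int, phi: float = -57.0, psi: float = -47.0,
                omega: float = 180.0) -> BackboneChain:
    """Synthetic idealized backbone with constant (phi, psi, omega).

    Defaults give a canonical alpha helix; used as a self-checking geometry
    fixture, not as a model of any real structure.
    """
    if n_res < 2:
        raise ValueError("need at least two residues")
    ncoords = [np.array([0.0, 0.0, 0.0])]
    cacoords = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    ang = math.radians(_ANGLE["N-CA-C"])
    ccoords = [cacoords[0] + _BOND["CA-C"]
               * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for _ in range(1, n_res):
        n_new = _place_atom(ncoords[-1], cacoords[-1], ccoords[-1],
                            _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca_new = _place_atom(cacoords[-1], ccoords[-1], n_new,
                             _BOND["N-CA"], _ANGLE["C-N-CA"], omega)
        c_new = _place_atom(ccoords[-1], n_new, ca_new,
                            _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        ncoords.append(n_new)
        cacoords.append(ca_new)
        ccoords.append(c_new)
    return BackboneChain("A", list(range(1, n_res + 1)),
                         np.array(ncoords), np.array(cacoords),
                         np.array(ccoords))


def coords_to_pdb(chain: BackboneChain, path) -> None:
    """Write a minimal PDB file of a backbone chain (N, CA, C as ALA)."""
    serial = 1
    with open(path, "w") as fh:
        for i in range(len(chain)):
            for name, xyz in (("N", chain.n[i]), ("CA", chain.ca[i]),
                              ("C", chain.c[i])):
                fh.write(
                    "ATOM  {serial:5d} {name:^4s}{alt}ALA {ch}{num:4d}{ins}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{el:>2s}\n".format(
                        serial=serial, name=name, alt=" ", ch=chain.chain_id,
                        num=chain.residue_numbers[i], ins=" ",
                        x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
                        el=name[0],
                    )
                )
                serial += 1
        fh.write("END\n")
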