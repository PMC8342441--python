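"""Shared fixtures: hand-written PDB text, synthetic backbone builders, rigid motions."""

from __future__ import annotations

import numpy as np
import pytest

from conformpath.structure_io import Atom, Structure


def pdb_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    x: float,
    y: float,
    z: float,
    alt_loc: str = " ",
    occupancy: float = 1.0,
    element: str = "C",
    het: bool = False,
    i_code: str = " ",
) -> str:
    rec = "HETATM" if het else "ATOM  "
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{rec}{serial:>5d} {name_field}{alt_loc}{res_name:>3s} {chain}{res_seq:>4d}{i_code}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Minimal hand-written 3-residue PDB file (CA-only)."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0),
        pdb_atom_line(2, "CA", "GLY", "A", 2, 4.0, 5.0, 6.0),
        pdb_atom_line(3, "CA", "LEU", "A", 3, 7.0, 8.0, 9.0),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rotation_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def structure_from_cas(coords, chain: str = "A", start_res: int = 1) -> Structure:
    """CA-only Structure from an (n, 3) coordinate array."""
    atoms = [
        Atom(
            name="CA", element="C", res_name="ALA", res_seq=start_res + i, i_code="",
            chain_id=chain, x=float(p[0]), y=float(p[1]), z=float(p[2]), serial=i + 1,
        )
        for i, p in enumerate(np.asarray(coords, dtype=float))
    ]
    return Structure(atoms)


# --------------------------------------------------------------------------
# Backbone construction from ideal internal coordinates (independent oracle
# for the dihedral code: build from target phi/psi, then invert).
# --------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d with bond |cd|, angle b-c-d, torsion a-b-c-d."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            -bond * np.sin(angle) * np.cos(torsion),
            -bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omega: float = 180.0) -> Structure:
    """Backbone (N, CA, C per residue) realizing the given interior phi/psi angles.

    ``phis[i]``/``psis[i]`` apply to residue i+1; phi of the first residue and
    psi of the last are unconstrained by construction.
    """
    n_res = len(phis)
    assert len(psis) == n_res
    coords = {}
    coords[(1, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(1, "CA")] = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.radians(_ANGLE["N-CA-C"])
    coords[(1, "C")] = coords[(1, "CA")] + _BOND["CA-C"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(1, n_res + 1):
        if i > 1:
            coords[(i, "C")] = _place(
                coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
                _BOND["CA-C"], _ANGLE["N-CA-C"], phis[i - 1],
            )
        if i < n_res:
            coords[(i + 1, "N")] = _place(
                coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
                _BOND["C-N"], _ANGLE["CA-C-N"], psis[i - 1],
            )
            coords[(i + 1, "CA")] = _place(
                coords[(i, "CA")], coords[(i, "C")], coords[(i + 1, "N")],
                _BOND["N-CA"], _ANGLE["C-N-CA"], omega,
            )
    atoms = []
    serial = 1
    for i in range(1, n_res + 1):
        for name in ("N", "CA", "C"):
            p = coords[(i, name)]
            atoms.append(
                Atom(
                    name=name, element=name[0], res_name="ALA", res_seq=i, i_code="",
                    chain_id="A", x=float(p[0]), y=float(p[1]), z=float(p[2]),
                    serial=serial,
                )
            )
            serial += 1
    return Structure(atoms)
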