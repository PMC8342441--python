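"""PDB structure I/O, Ballesteros–Weinstein position resolution, Kabsch superposition.

Only Cα atoms are consumed downstream; full atom records are retained for
provenance (including HETATM records, which are flagged so fusion proteins
and ligands can be excluded).
"""

from __future__ import annotations

import math
import os
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "BWMap",
    "PDBParseError",
    "MissingAtomError",
    "read_pdb",
    "write_pdb",
    "load_bw_table",
    "default_bw_table",
    "resolve_bw",
    "kabsch_superpose",
    "fetch_structure",
]


class PDBParseError(ValueError):
    """Raised when an ATOM/HETATM record cannot be parsed (carries line number)."""


class MissingAtomError(LookupError):
    """Raised when a requested atom (typically a Cα) is absent from a structure."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_name: str
    res_seq: int
    i_code: str
    chain_id: str
    x: float
    y: float
    z: float
    alt_loc: str = ""
    occupancy: float = 1.0
    het: bool = False
    serial: int = 0

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """Ordered atom records of a single model, with Cα lookup after altloc resolution."""

    atoms: list[Atom]
    model_id: int = 1
    _ca_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not (math.isfinite(a.x) and math.isfinite(a.y) and math.isfinite(a.z)):
                raise ValueError(f"non-finite coordinate in atom serial {a.serial}")
        self._ca_index = None

    # -- altloc resolution: highest occupancy wins, ties broken by altloc letter --
    @staticmethod
    def _resolve_altloc(candidates: list[Atom]) -> Atom:
        return min(candidates, key=lambda a: (-a.occupancy, a.alt_loc))

    def _build_ca_index(self) -> dict:
        groups: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            if a.name == "CA" and not a.het:
                groups.setdefault((a.chain_id, a.res_seq, a.i_code), []).append(a)
        return {key: self._resolve_altloc(g) for key, g in groups.items()}

    def ca(self, chain_id: str, res_seq: int, i_code: str = "") -> Atom:
        if self._ca_index is None:
            self._ca_index = self._build_ca_index()
        try:
            return self._ca_index[(chain_id, res_seq, i_code)]
        except KeyError:
            raise MissingAtomError(
                f"no CA atom for chain {chain_id!r} residue {res_seq}{i_code!r}"
            ) from None

    def ca_coord(self, chain_id: str, res_seq: int, i_code: str = "") -> np.ndarray:
        return self.ca(chain_id, res_seq, i_code).coord

    def atom(self, chain_id: str, res_seq: int, name: str, i_code: str = "") -> Atom:
        candidates = [
            a
            for a in self.atoms
            if a.chain_id == chain_id
            and a.res_seq == res_seq
            and a.i_code == i_code
            and a.name == name
            and not a.het
        ]
        if not candidates:
            raise MissingAtomError(
                f"no {name} atom for chain {chain_id!r} residue {res_seq}{i_code!r}"
            )
        return self._resolve_altloc(candidates)

    def residues(self, chain_id: str) -> list[tuple[int, str]]:
        """(res_seq, i_code) pairs of polymer residues in file order for one chain."""
        seen, out = set(), []
        for a in self.atoms:
            if a.het or a.chain_id != chain_id:
                continue
            key = (a.res_seq, a.i_code)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def chains(self) -> list[str]:
        seen, out = set(), []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.add(a.chain_id)
                out.append(a.chain_id)
        return out

    def without_het(self) -> "Structure":
        return Structure([a for a in self.atoms if not a.het], self.model_id)


def _parse_atom_line(line: str, lineno: int, het: bool) -> Atom:
    line = line.rstrip("\n").ljust(80)
    try:
        return Atom(
            serial=int(line[6:11]),
            name=line[12:16].strip(),
            alt_loc=line[16].strip(),
            res_name=line[17:20].strip(),
            chain_id=line[21].strip(),
            res_seq=int(line[22:26]),
            i_code=line[26].strip(),
            x=float(line[30:38]),
            y=float(line[38:46]),
            z=float(line[46:54]),
            occupancy=float(line[54:60]) if line[54:60].strip() else 1.0,
            element=line[76:78].strip(),
            het=het,
        )
    except ValueError as exc:
        raise PDBParseError(f"malformed {'HETATM' if het else 'ATOM'} record at line {lineno}: {exc}") from exc


def read_pdb(path, model: int | None = None) -> Structure | list[Structure]:
    """Parse a PDB file (ATOM/HETATM/MODEL/ENDMDL).

    Returns the first (or requested) model as a :class:`Structure`; pass
    ``model=None`` on a multi-model file to get the first model, or use
    :func:`read_pdb_models` for all models.
    """
    models = read_pdb_models(path)
    if model is None:
        return models[0]
    for s in models:
        if s.model_id == model:
            return s
    raise MissingAtomError(f"model {model} not found in {path}")


def read_pdb_models(path) -> list[Structure]:
    """Parse every model of a PDB file into a list of Structures."""
    path = Path(path)
    models: list[Structure] = []
    atoms: list[Atom] = []
    model_id = 1
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if atoms:
                    models.append(Structure(atoms, model_id))
                    atoms = []
                saw_model_record = True
                try:
                    model_id = int(line[10:14])
                except ValueError:
                    model_id = len(models) + 1
            elif rec == "ENDMDL":
                models.append(Structure(atoms, model_id))
                atoms = []
                model_id += 1
            elif rec == "ATOM  ":
                atoms.append(_parse_atom_line(line, lineno, het=False))
            elif rec == "HETATM":
                atoms.append(_parse_atom_line(line, lineno, het=True))
    if atoms or not models:
        if not atoms and not models:
            raise PDBParseError(f"no ATOM/HETATM records found in {path}")
        models.append(Structure(atoms, model_id if saw_model_record else 1))
    return models


def write_pdb(structure: Structure, path) -> None:
    """Emit ATOM/HETATM records for the fields the reader consumes (round-trip safe)."""
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            rec = "HETATM" if a.het else "ATOM  "
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"{rec}{a.serial or i:>5d} {name}{a.alt_loc or ' ':1s}"
                f"{a.res_name:>3s} {a.chain_id or ' ':1s}{a.res_seq:>4d}{a.i_code or ' ':1s}"
                f"   {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


# --------------------------------------------------------------------------
# Ballesteros–Weinstein position mapping
# --------------------------------------------------------------------------

class BWMap(dict):
    """Mapping from BW position string (e.g. ``"5.55"``) to ``(chain_id, res_seq)``.

    The mapping must be injective: two positions may not point at the same residue.
    """

    def __init__(self, entries: Mapping[str, tuple[str, int]] = ()):
        super().__init__(entries)
        self._check_injective()

    def _check_injective(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for pos, target in self.items():
            target = tuple(target)
            if target in seen:
                raise ValueError(
                    f"BW map not injective: positions {seen[target]!r} and {pos!r} "
                    f"both map to {target}"
                )
            seen[target] = pos


def load_bw_table(path) -> BWMap:
    """Load a two-column table ``position<TAB>chain:resnum`` (# comments allowed)."""
    entries: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                pos, target = line.split()
                chain, resnum = target.split(":")
                entries[pos] = (chain, int(resnum))
            except ValueError as exc:
                raise ValueError(f"malformed BW table line {lineno}: {raw!r}") from exc
    return BWMap(entries)


def default_bw_table() -> BWMap:
    """Packaged BW table for the human AT1 receptor (GPCRdb generic numbering)."""
    return load_bw_table(Path(__file__).parent / "data" / "at1r_bw.tsv")


def resolve_bw(structure: Structure, bw_table: BWMap) -> BWMap:
    """Validate that every BW position has a Cα in the structure.

    Raises :class:`MissingAtomError` naming the first unresolvable position.
    """
    for pos, (chain, res_seq) in bw_table.items():
        try:
            structure.ca(chain, res_seq)
        except MissingAtomError as exc:
            raise MissingAtomError(f"BW position {pos!r}: {exc}") from None
    return BWMap(bw_table)


# --------------------------------------------------------------------------
# Kabsch superposition
# --------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``reference``.
    The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    p, q = mobile - mc, reference - rc
    if np.linalg.matrix_rank(p, tol=1e-10) < 2 or np.linalg.matrix_rank(q, tol=1e-10) < 2:
        raise ValueError("degenerate (rank-deficient) point set")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = rc - rotation @ mc
    moved = p @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rotation, translation, rmsd


# --------------------------------------------------------------------------
# Structure retrieval (worked-example inputs)
# --------------------------------------------------------------------------

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_structure(
    pdb_id: str,
    search_dirs: Sequence[os.PathLike | str] = (),
    allow_download: bool = False,
    timeout: float = 30.0,
) -> Structure:
    """Load a PDB entry from local search paths, optionally downloading it.

    Search order: explicit ``search_dirs``, ``$CONFORMPATH_PDB_DIR``, then
    ``data/structures/`` relative to the current working directory. Download
    from RCSB is attempted only when ``allow_download`` is set.
    """
    pdb_id = pdb_id.upper()
    candidates = [Path(d) for d in search_dirs]
    env_dir = os.environ.get("CONFORMPATH_PDB_DIR")
    if env_dir:
        candidates.append(Path(env_dir))
    candidates.append(Path("data") / "structures")
    for d in candidates:
        path = d / f"{pdb_id}.pdb"
        if path.is_file():
            return read_pdb(path)
    if allow_download:
        target = candidates[-1]
        target.mkdir(parents=True, exist_ok=True)
        path = target / f"{pdb_id}.pdb"
        urllib.request.urlretrieve(_RCSB_URL.format(pdb_id=pdb_id), path)  # noqa: S310
        return read_pdb(path)
    raise FileNotFoundError(
        f"{pdb_id}.pdb not found in {[str(c) for c in candidates]}; "
        "download it once or pass allow_download=True"
    )
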