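"""Reaction-coordinate geometry for GPCR activation motifs.

Computes the coordinates used to characterise muscarinic-receptor activation:
atom-pair distances (the Arg^3.50–Glu^6.30 ionic lock between the Arg Cζ and
Glu Cδ charge-centre atoms, and the Tyr^5.58–Tyr^7.53 hydroxyl-oxygen
distance) and side-chain dihedral angles (χ1, χ2 of the Trp^6.48 toggle
switch), from PDB structures or any frame source that can resolve a named
atom to coordinates.

Conventions
-----------
* Distances in Å, dihedrals in degrees on (−180, 180] with the standard
  atan2 sign convention; dihedrals are invariant under rigid motion and flip
  sign under mirror reflection.
* χ1 = N–CA–CB–CG and χ2 = CA–CB–CG–CD1 for tryptophan (IUPAC atom names;
  the CD1-vs-CD2 branch ambiguity for χ2 is resolved to CD1).
* PDB reading keeps the first model only and altloc ' ' or 'A'; residue
  numbering is taken verbatim, insertion codes preserved.  Parsing is backed
  by Bio.PDB behind this module's interface.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, GeometryError, InputError, SelectionError

__all__ = [
    "Atom",
    "Structure",
    "DistanceRC",
    "DihedralRC",
    "RCSeries",
    "read_pdb",
    "atom_distance",
    "dihedral_angle",
    "trp_chi_selections",
    "evaluate_rc",
    "extract_rc_series",
    "place_atom",
    "synthetic_receptor_fragment",
    "frames_from_mdanalysis",
]

AtomKey = tuple[str, int, str]  # (chain, residue number, atom name)


@dataclass(frozen=True)
class Atom:
    name: str
    res_name: str
    res_seq: int
    chain: str
    xyz: tuple[float, float, float]
    icode: str = ""
    element: str = ""


@dataclass
class Structure:
    """A flat, single-model collection of atoms with (chain, resseq, name) lookup."""

    atoms: list[Atom]
    source: str = ""

    def __post_init__(self) -> None:
        index: dict[AtomKey, list[Atom]] = {}
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.xyz):
                raise InputError(f"non-finite coordinates for atom {a}")
            index.setdefault((a.chain, a.res_seq, a.name), []).append(a)
        self._index = index

    def atom_xyz(self, key: AtomKey) -> np.ndarray:
        hits = self._index.get(tuple(key), [])
        if len(hits) != 1:
            raise SelectionError(
                f"selection (chain={key[0]!r}, resseq={key[1]}, atom={key[2]!r}) "
                f"resolved to {len(hits)} atoms in {self.source or 'structure'}"
            )
        return np.asarray(hits[0].xyz, dtype=float)

    def residue_atoms(self, chain: str, res_seq: int) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain and a.res_seq == res_seq]

    def residues(self) -> dict[tuple[str, int], str]:
        out: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.res_seq), a.res_name)
        return out


@dataclass(frozen=True)
class DistanceRC:
    """Distance between two uniquely resolving atoms, reported in Å."""

    selection_a: AtomKey
    selection_b: AtomKey
    name: str = "distance"

    unit = "angstrom"
    periodic = False


@dataclass(frozen=True)
class DihedralRC:
    """Torsion over four atoms, reported in degrees on (−180, 180]."""

    selections: tuple[AtomKey, AtomKey, AtomKey, AtomKey]
    angle_name: str = "custom"

    unit = "degree"
    periodic = True

    def __post_init__(self) -> None:
        if len(set(self.selections)) != 4:
            raise SelectionError("dihedral requires four distinct atom selections")


@dataclass
class RCSeries:
    """A scalar reaction-coordinate time series.

    ``delta_v`` optionally carries the per-frame boost energy (kcal/mol)
    needed for energetic reweighting; ``stride`` is the time between retained
    frames in the trajectory's time unit.
    """

    values: np.ndarray
    unit: str = "angstrom"
    periodic: bool = False
    period: float = 360.0
    delta_v: np.ndarray | None = None
    stride: float = 1.0
    name: str = "rc"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InputError("RCSeries values must be a non-empty 1D array")
        if self.periodic:
            if not (self.period > 0):
                raise InputError("periodic RCSeries needs period > 0")
            self.values = wrap_periodic(self.values, self.period)
        if self.delta_v is not None:
            self.delta_v = np.asarray(self.delta_v, dtype=float)
            if self.delta_v.shape != self.values.shape:
                raise InputError("delta_v length must match values length")
            if np.any(self.delta_v < 0):
                raise InputError("delta_v must be non-negative (boost energies)")

    def __len__(self) -> int:
        return self.values.size

    # -- TSV round trip (bit-exact via 17-significant-digit floats) ---------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# amdkit rc-series\n")
            fh.write(f"# name: {self.name}\n")
            fh.write(f"# unit: {self.unit}\n")
            fh.write(f"# periodic: {str(self.periodic).lower()}\n")
            fh.write(f"# period: {self.period:.17g}\n")
            fh.write(f"# stride: {self.stride:.17g}\n")
            for key, val in sorted(self.metadata.items()):
                fh.write(f"# meta:{key}: {val}\n")
            cols = "value\tdelta_v" if self.delta_v is not None else "value"
            fh.write(f"# columns: {cols}\n")
            if self.delta_v is not None:
                for v, d in zip(self.values, self.delta_v):
                    fh.write(f"{v:.17g}\t{d:.17g}\n")
            else:
                for v in self.values:
                    fh.write(f"{v:.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RCSeries":
        header: dict[str, str] = {}
        meta: dict[str, str] = {}
        values: list[float] = []
        dv: list[float] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if ":" in body:
                        key, _, val = body.partition(":")
                        key = key.strip()
                        if key == "meta":
                            mkey, _, mval = val.strip().partition(":")
                            meta[mkey.strip()] = mval.strip()
                        else:
                            header[key] = val.strip()
                    continue
                parts = line.split("\t")
                try:
                    values.append(float(parts[0]))
                    if len(parts) > 1:
                        dv.append(float(parts[1]))
                except ValueError as exc:
                    raise FormatError(f"bad numeric field {parts!r}", lineno) from exc
        if not values:
            raise FormatError(f"no data rows in {path}")
        if dv and len(dv) != len(values):
            raise FormatError(f"inconsistent delta_v column in {path}")
        return cls(
            values=np.array(values),
            unit=header.get("unit", "angstrom"),
            periodic=header.get("periodic", "false") == "true",
            period=float(header.get("period", 360.0)),
            delta_v=np.array(dv) if dv else None,
            stride=float(header.get("stride", 1.0)),
            name=header.get("name", "rc"),
            metadata=meta,
        )


def wrap_periodic(values: np.ndarray | float, period: float = 360.0):
    """Wrap angles into the half-open interval (−period/2, period/2]."""
    v = np.asarray(values, dtype=float)
    half = period / 2.0
    wrapped = v - period * np.ceil((v - half) / period)
    # ceil maps the left edge −half to −half; fold it onto +half
    wrapped = np.where(wrapped <= -half, wrapped + period, wrapped)
    return wrapped if np.ndim(values) else float(wrapped)


# ---------------------------------------------------------------------------
# PDB reading (Bio.PDB behind the interface)
# ---------------------------------------------------------------------------

def _prescan_pdb_lines(lines: Iterable[str]) -> None:
    """Line-numbered coordinate validation ahead of the Bio.PDB parse."""
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line.rstrip("\n")) < 54:
                raise FormatError("truncated ATOM/HETATM record", lineno)
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise FormatError(
                    f"unparseable coordinates {line[30:54]!r}", lineno
                ) from exc


def read_pdb(source: str | Path | io.StringIO) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    First model only; altloc ' ' or 'A' retained; insertion codes preserved.
    Raises :class:`FormatError` with a line number for malformed coordinate
    records.
    """
    from Bio.PDB import PDBParser

    if isinstance(source, io.StringIO):
        text = source.getvalue()
        label = "<stringio>"
    else:
        path = Path(source)
        text = path.read_text()
        label = str(path)
    _prescan_pdb_lines(text.splitlines())

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure("pdb", io.StringIO(text))
    models = list(bio_structure.get_models())
    if not models:
        raise FormatError(f"no models found in {label}")
    model = models[0]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            _, res_seq, icode = residue.get_id()
            for atom in residue.get_unpacked_list():
                if atom.get_altloc() not in (" ", "", "A"):
                    continue
                x, y, z = (float(c) for c in atom.get_coord())
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        res_name=residue.get_resname().strip(),
                        res_seq=int(res_seq),
                        chain=chain.id.strip() or chain.id,
                        xyz=(x, y, z),
                        icode=icode.strip(),
                        element=(atom.element or "").strip(),
                    )
                )
    if not atoms:
        raise FormatError(f"no atoms with coordinates in {label}")
    return Structure(atoms=atoms, source=label)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def atom_distance(frame_or_structure, rc: DistanceRC) -> float:
    """Euclidean distance in Å between the two selected atoms."""
    a = np.asarray(frame_or_structure.atom_xyz(rc.selection_a), dtype=float)
    b = np.asarray(frame_or_structure.atom_xyz(rc.selection_b), dtype=float)
    return float(np.linalg.norm(a - b))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees on (−180, 180].

    Standard atan2 construction: with bond vectors b1 = p2−p1, b2 = p3−p2,
    b3 = p4−p3, the angle is atan2(|b2|·(b1×b2)·b3, (b1×b2)·(b2×b3)).
    Invariant under rigid rotation/translation; sign flips under reflection.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for name, b in (("p1-p2", b1), ("p2-p3", b2), ("p3-p4", b3)):
        if np.linalg.norm(b) < 1e-10:
            raise GeometryError(f"coincident consecutive points across bond {name}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear point triple; dihedral undefined")
    y = float(np.dot(n1, b3)) * float(np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


_CHI1_ATOMS = ("N", "CA", "CB", "CG")
_CHI2_ATOMS = ("CA", "CB", "CG", "CD1")


def trp_chi_selections(
    structure: Structure, res_seq: int, chain: str | None = None
) -> tuple[DihedralRC, DihedralRC]:
    """χ1/χ2 dihedral selections for a tryptophan residue.

    χ1 = N–CA–CB–CG, χ2 = CA–CB–CG–CD1.  Raises :class:`SelectionError` if
    the residue is not TRP or a required atom is absent.
    """
    candidates = sorted(
        {(c, r) for (c, r) in structure.residues() if r == res_seq}
        if chain is None
        else {(chain, res_seq)}
    )
    if chain is None and len(candidates) != 1:
        raise SelectionError(
            f"residue {res_seq} matches {len(candidates)} chains; pass chain explicitly"
        )
    chain_id, _ = candidates[0]
    atoms = structure.residue_atoms(chain_id, res_seq)
    if not atoms:
        raise SelectionError(f"no residue {res_seq} in chain {chain_id!r}")
    res_name = atoms[0].res_name
    if res_name != "TRP":
        raise SelectionError(
            f"residue {chain_id}:{res_seq} is {res_name}, not TRP"
        )
    present = {a.name for a in atoms}
    missing = [n for n in set(_CHI1_ATOMS + _CHI2_ATOMS) if n not in present]
    if missing:
        raise SelectionError(
            f"TRP {chain_id}:{res_seq} missing atoms {sorted(missing)}"
        )
    chi1 = DihedralRC(
        selections=tuple((chain_id, res_seq, n) for n in _CHI1_ATOMS),
        angle_name="chi1",
    )
    chi2 = DihedralRC(
        selections=tuple((chain_id, res_seq, n) for n in _CHI2_ATOMS),
        angle_name="chi2",
    )
    return chi1, chi2


def evaluate_rc(frame, rc: DistanceRC | DihedralRC) -> float:
    """Evaluate one reaction coordinate on one frame/structure."""
    if isinstance(rc, DistanceRC):
        return atom_distance(frame, rc)
    if isinstance(rc, DihedralRC):
        pts = [frame.atom_xyz(sel) for sel in rc.selections]
        return dihedral_angle(*pts)
    raise InputError(f"unsupported reaction-coordinate type {type(rc).__name__}")


def extract_rc_series(
    frames: Sequence, rc: DistanceRC | DihedralRC, stride: int = 1
) -> RCSeries:
    """Evaluate a reaction coordinate on every ``stride``-th frame.

    Frames 0, stride, 2·stride, … are retained.  Per-frame boost energies are
    carried through when every retained frame exposes a ``delta_v`` attribute.
    Raises the underlying selection/geometry error naming the frame index.
    """
    if stride < 1:
        raise InputError(f"stride must be >= 1, got {stride}")
    values: list[float] = []
    dvs: list[float] = []
    have_dv = True
    for idx in range(0, len(frames), stride):
        frame = frames[idx]
        try:
            values.append(evaluate_rc(frame, rc))
        except (SelectionError, GeometryError) as exc:
            raise type(exc)(f"frame {idx}: {exc}") from exc
        dv = getattr(frame, "delta_v", None)
        if dv is None:
            have_dv = False
        elif have_dv:
            dvs.append(float(dv))
    return RCSeries(
        values=np.array(values),
        unit=rc.unit,
        periodic=rc.periodic,
        period=360.0,
        delta_v=np.array(dvs) if (have_dv and dvs) else None,
        stride=float(stride),
        name=getattr(rc, "angle_name", getattr(rc, "name", "rc")),
    )


# ---------------------------------------------------------------------------
# Internal-coordinate placement and the synthetic structure stand-in
# ---------------------------------------------------------------------------

def place_atom(a, b, c, bond_length: float, bond_angle: float, dihedral: float) -> np.ndarray:
    """Place atom D given A, B, C plus |CD|, angle(BCD) and dihedral(A,B,C,D).

    Natural-extension-reference-frame construction; the returned point
    satisfies ``dihedral_angle(a, b, c, d) == dihedral`` under this module's
    sign convention (angles in degrees).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(bond_angle)
    phi = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear reference atoms; placement frame undefined")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * math.cos(theta),
            bond_length * math.sin(theta) * math.cos(phi),
            bond_length * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _format_pdb_atom(serial: int, atom: Atom) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    elem = atom.element or atom.name[0]
    x, y, z = atom.xyz
    return (
        f"ATOM  {serial:5d} {name:4s} {atom.res_name:>3s} {atom.chain:1s}"
        f"{atom.res_seq:4d}{atom.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {elem:>2s}"
    )


def synthetic_receptor_fragment(
    tyr_oh_distance: float = 12.6,
    trp_chi1: float = -75.0,
    trp_chi2: float = 40.0,
) -> str:
    """PDB text for a SYNTHETIC five-residue muscarinic-motif stand-in.

    This is not an experimental structure.  It is a programmatically built
    fragment carrying the residues of the M2-receptor activation motifs —
    Arg121 (ionic-lock Cζ), Glu382 (ionic-lock Cδ), Trp400 (toggle switch),
    Tyr206 and Tyr440 (intracellular hydrogen-bond pair) — with idealised
    side-chain geometry.  By construction the Tyr206 OH–Tyr440 OH distance
    equals ``tyr_oh_distance`` (default the 12.6 Å of the inactive
    antagonist-bound crystal geometry) and the Trp400 χ1/χ2 dihedrals equal
    ``trp_chi1``/``trp_chi2`` (default the inactive rotamer −75°/40°).  It
    exists so the PDB-parse → selection → distance/dihedral pipeline can be
    exercised end-to-end without downloading coordinates.
    """
    atoms: list[Atom] = []

    def add(name, res_name, res_seq, xyz, element=""):
        atoms.append(
            Atom(
                name=name,
                res_name=res_name,
                res_seq=res_seq,
                chain="A",
                xyz=tuple(round(float(c), 3) for c in xyz),
                element=element or name[0],
            )
        )

    # ARG 121 — ionic-lock charge centre at CZ.
    add("N", "ARG", 121, (0.0, 0.0, 0.0), "N")
    add("CA", "ARG", 121, (1.46, 0.0, 0.0), "C")
    add("CB", "ARG", 121, (2.0, 1.43, 0.0), "C")
    add("CZ", "ARG", 121, (4.2, 3.1, 1.2), "C")
    # GLU 382 — ionic-lock charge centre at CD, placed ~10 Å from Arg CZ
    # (the crystal conformation has an open ionic lock).
    add("N", "GLU", 382, (10.0, 10.0, 0.0), "N")
    add("CA", "GLU", 382, (11.46, 10.0, 0.0), "C")
    add("CB", "GLU", 382, (12.0, 11.43, 0.0), "C")
    add("CD", "GLU", 382, (12.4, 9.6, 4.0), "C")

    # TYR 206 / TYR 440 — hydroxyl oxygens exactly tyr_oh_distance apart.
    oh206 = np.array([20.0, 0.0, 0.0])
    oh440 = oh206 + np.array([tyr_oh_distance, 0.0, 0.0])
    add("N", "TYR", 206, oh206 + (-4.0, 1.0, 0.5), "N")
    add("CA", "TYR", 206, oh206 + (-2.8, 0.4, 1.2), "C")
    add("CB", "TYR", 206, oh206 + (-1.9, 1.1, 0.2), "C")
    add("OH", "TYR", 206, oh206, "O")
    add("N", "TYR", 440, oh440 + (4.0, -1.0, 0.5), "N")
    add("CA", "TYR", 440, oh440 + (2.8, -0.4, 1.2), "C")
    add("CB", "TYR", 440, oh440 + (1.9, -1.1, 0.2), "C")
    add("OH", "TYR", 440, oh440, "O")

    # TRP 400 — toggle switch, built by internal coordinates so that the
    # χ1/χ2 torsions take the requested values before coordinate rounding.
    origin = np.array([0.0, 20.0, 10.0])
    n = origin
    ca = origin + np.array([1.46, 0.0, 0.0])
    theta = math.radians(110.5)
    cb = ca + 1.53 * np.array([-math.cos(theta), math.sin(theta), 0.0])
    cg = place_atom(n, ca, cb, 1.50, 113.6, trp_chi1)
    cd1 = place_atom(ca, cb, cg, 1.37, 127.0, trp_chi2)
    cd2 = place_atom(ca, cb, cg, 1.43, 126.6, trp_chi2 - 180.0)
    add("N", "TRP", 400, n, "N")
    add("CA", "TRP", 400, ca, "C")
    add("CB", "TRP", 400, cb, "C")
    add("CG", "TRP", 400, cg, "C")
    add("CD1", "TRP", 400, cd1, "C")
    add("CD2", "TRP", 400, cd2, "C")

    lines = [
        "REMARK   6 SYNTHETIC COORDINATES GENERATED BY AMDKIT -- NOT AN",
        "REMARK   6 EXPERIMENTAL STRUCTURE. FIVE-RESIDUE STAND-IN FOR THE",
        "REMARK   6 M2 MUSCARINIC RECEPTOR ACTIVATION MOTIFS WITH THE",
        "REMARK   6 TYR206 OH - TYR440 OH DISTANCE AND TRP400 CHI1/CHI2",
        "REMARK   6 ROTAMER SET BY CONSTRUCTION.",
    ]
    lines += [_format_pdb_atom(i + 1, a) for i, a in enumerate(atoms)]
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Thin trajectory-frame adapter (DCD/XTC via MDAnalysis)
# ---------------------------------------------------------------------------

class _MDAFrame:
    """One trajectory frame exposing the ``atom_xyz(selection)`` contract."""

    __slots__ = ("_coords", "_lookup", "delta_v")

    def __init__(self, coords: np.ndarray, lookup: dict[AtomKey, int], delta_v=None):
        self._coords = coords
        self._lookup = lookup
        self.delta_v = delta_v

    def atom_xyz(self, key: AtomKey) -> np.ndarray:
        idx = self._lookup.get(tuple(key))
        if idx is None:
            raise SelectionError(f"selection {key!r} not found in trajectory topology")
        return self._coords[idx]


def frames_from_mdanalysis(universe, delta_v: Sequence[float] | None = None):
    """Adapt an MDAnalysis Universe (PDB/DCD/XTC...) to amdkit frames.

    Yields frame objects satisfying the ``atom_xyz((chain, resseq, name))``
    contract used by :func:`extract_rc_series`; ``delta_v`` optionally
    attaches per-frame boost energies.  MDAnalysis is imported lazily so the
    core package has no hard dependency on it.
    """
    lookup: dict[AtomKey, int] = {}
    for i, atom in enumerate(universe.atoms):
        chain = getattr(atom, "chainID", "") or getattr(atom, "segid", "")
        key = (str(chain).strip(), int(atom.resid), str(atom.name))
        if key not in lookup:
            lookup[key] = i
    frames = []
    for t, ts in enumerate(universe.trajectory):
        dv = None if delta_v is None else float(delta_v[t])
        frames.append(_MDAFrame(ts.positions.copy().astype(float), lookup, dv))
    return frames
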