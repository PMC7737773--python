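"""Protein structure parsing, mutation grammar, solvent accessibility and
trajectory output.

All residue positions use *author* numbering (with insertion codes) exactly as
they appear in the PDB file; no renumbering is ever performed. Alternate
locations are resolved to a single atom per (chain, residue, name) by keeping
the highest-occupancy conformer (ties: first listed). Only the first MODEL is
read unless another is requested. Waters are dropped; hydrogens and other
HETATM groups are retained.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "MutationSpec",
    "MultiMutation",
    "ResidueHandle",
    "PDBParseError",
    "MutationFormatError",
    "SiteNotFoundError",
    "WildTypeMismatchError",
    "parse_structure",
    "parse_mutation",
    "parse_multi",
    "locate_site",
    "relative_solvent_accessibility",
    "rsa_class",
    "write_pdb",
    "write_trajectory",
    "STANDARD_AA3",
    "MAX_ASA",
    "BACKBONE_NAMES",
]

STANDARD_AA1 = set("ACDEFGHIKLMNPQRSTVWY")
STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "DOD"}
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

#: Theoretical maximum accessible surface areas (A^2) per residue in a
#: Gly-X-Gly tripeptide (Tien et al. 2013, theoretical column). Denominator
#: of relative solvent accessibility.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# van der Waals radii (A) by element for Shrake-Rupley
_VDW = {"H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
        "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90}
_VDW_DEFAULT = 1.70


class PDBParseError(ValueError):
    """Input text is not a usable PDB structure."""


class MutationFormatError(ValueError):
    """Mutation string does not follow the WT-position-MUT grammar."""


class SiteNotFoundError(KeyError):
    """No residue at the requested chain/position/insertion code."""


class WildTypeMismatchError(KeyError):
    """Residue exists but its type differs from the stated wild type
    (wrong numbering or wrong chain)."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str  # "" when absent
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Structure:
    """Flat, ordered atom container for one model of a PDB entry."""

    atoms: list[Atom]
    model_index: int = 0
    source_id: str = ""
    _kdtree: Optional[cKDTree] = field(default=None, repr=False, compare=False)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def kdtree(self) -> cKDTree:
        if self._kdtree is None:
            self._kdtree = cKDTree(self.coords)
        return self._kdtree

    def residues(self) -> list["ResidueHandle"]:
        """Residue handles in file order."""
        out, seen = [], {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_seq, a.insertion_code, a.residue_name)
            if key not in seen:
                seen[key] = ResidueHandle(a.chain_id, a.residue_seq,
                                          a.insertion_code, a.residue_name, [])
                out.append(seen[key])
            seen[key].atom_indices.append(i)
        return out

    def n_protein_residues(self) -> int:
        return sum(1 for r in self.residues() if r.name in STANDARD_AA3)

    def ca_indices(self) -> list[int]:
        """Index of the Calpha atom of each standard residue, file order."""
        out = []
        for r in self.residues():
            if r.name not in STANDARD_AA3:
                continue
            for i in r.atom_indices:
                if self.atoms[i].name == "CA":
                    out.append(i)
                    break
        return out


@dataclass
class ResidueHandle:
    chain_id: str
    residue_seq: int
    insertion_code: str
    name: str
    atom_indices: list[int]

    @property
    def one_letter(self) -> Optional[str]:
        return protein_letters_3to1.get(self.name)

    def atom_index(self, structure: Structure, atom_name: str) -> Optional[int]:
        for i in self.atom_indices:
            if structure.atoms[i].name == atom_name:
                return i
        return None


@dataclass(frozen=True)
class MutationSpec:
    chain: str
    wt: str
    position: int
    mut: str
    icode: str = ""

    def __post_init__(self):
        if self.wt not in STANDARD_AA1 or self.mut not in STANDARD_AA1:
            raise MutationFormatError(
                f"{self.wt}{self.position}{self.mut}: amino acids must be one of "
                "the 20 standard one-letter codes")
        if self.wt == self.mut:
            raise MutationFormatError(
                f"{self.wt}{self.position}{self.mut}: null mutation (wt == mut)")

    @property
    def site_key(self):
        return (self.chain, self.position, self.icode)

    def __str__(self) -> str:
        return f"{self.chain} {self.wt}{self.position}{self.icode}{self.mut}"


@dataclass(frozen=True)
class MultiMutation:
    specs: tuple[MutationSpec, ...]

    def __post_init__(self):
        if not 1 <= len(self.specs) <= 3:
            raise MutationFormatError(
                f"{len(self.specs)} mutations given; up to three point mutations "
                "(single, double or triple mutants) are supported")
        keys = [s.site_key for s in self.specs]
        if len(set(keys)) != len(keys):
            raise MutationFormatError("duplicate mutation site in multi-mutation")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __str__(self) -> str:
        return ",".join(str(s) for s in self.specs)


# ---------------------------------------------------------------------------
# parsing

def parse_structure(pdb_text: str, model: int = 0, source_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Waters are excluded, hydrogens kept, altlocs resolved (highest occupancy,
    ties first-listed) and only the requested MODEL (default: first) is read.
    """
    if "ATOM" not in pdb_text:
        raise PDBParseError("no ATOM records in input")
    parser = PDBParser(QUIET=True)
    try:
        entity = parser.get_structure(source_id or "structure", io.StringIO(pdb_text))
    except Exception as exc:  # Bio.PDB raises assorted types
        raise PDBParseError(f"unparseable PDB text: {exc}") from exc
    models = list(entity.get_models())
    if not models:
        raise PDBParseError("no models in input")
    if model >= len(models):
        raise PDBParseError(f"model index {model} out of range ({len(models)} models)")
    selected = models[model]

    atoms: list[Atom] = []
    for chain in selected:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.resname.strip()
            if resname in WATER_NAMES:
                continue
            # group altlocs by atom name, keep max occupancy / first listed
            by_name: dict[str, list] = {}
            for batom in residue.get_unpacked_list():
                by_name.setdefault(batom.get_name(), []).append(batom)
            for name, variants in by_name.items():
                best = max(enumerate(variants),
                           key=lambda kv: (kv[1].get_occupancy() or 0.0, -kv[0]))[1]
                element = (best.element or name[0]).strip()
                atoms.append(Atom(
                    serial=best.get_serial_number() or len(atoms) + 1,
                    name=name,
                    element=element or "X",
                    residue_name=resname,
                    chain_id=chain.id,
                    residue_seq=int(resseq),
                    insertion_code="" if icode == " " else icode,
                    coords=np.asarray(best.get_coord(), dtype=float),
                    occupancy=float(best.get_occupancy() or 1.0),
                    is_hetero=(hetflag.strip() != ""),
                ))
    if not atoms:
        raise PDBParseError("no atoms after filtering")
    structure = Structure(atoms=atoms, model_index=model, source_id=source_id)
    if structure.n_protein_residues() == 0:
        raise PDBParseError("structure contains no standard protein residue")
    return structure


_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation(code: str, chain: str, icode: str = "") -> MutationSpec:
    """Parse a mutation string of the form WT + position + MUT, e.g. ``W43F``."""
    m = _MUT_RE.match(code.strip())
    if m is None:
        raise MutationFormatError(
            f"{code!r}: expected wild-type letter, position, mutant letter (e.g. W43F)")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    if not chain or len(chain.strip()) != 1:
        raise MutationFormatError(f"chain must be a single character, got {chain!r}")
    return MutationSpec(chain=chain.strip(), wt=wt, position=pos, mut=mut, icode=icode)


def parse_multi(code_list: str, default_chain: Optional[str] = None) -> MultiMutation:
    """Parse comma-separated mutations, each ``CHAIN WTposMUT`` or ``WTposMUT``.

    At most three sites (double and triple mutants plus singles) are supported.
    """
    entries = [e.strip() for e in code_list.split(",") if e.strip()]
    if not entries:
        raise MutationFormatError("empty mutation list")
    if len(entries) > 3:
        raise MutationFormatError(
            f"{len(entries)} mutations given; up to three point mutations are supported")
    specs = []
    for entry in entries:
        parts = entry.split()
        if len(parts) == 2:
            chain, code = parts
        elif len(parts) == 1:
            if default_chain is None:
                raise MutationFormatError(
                    f"{entry!r}: no chain given and no default chain set")
            chain, code = default_chain, parts[0]
        else:
            raise MutationFormatError(f"cannot parse mutation entry {entry!r}")
        specs.append(parse_mutation(code, chain))
    return MultiMutation(specs=tuple(specs))


def locate_site(structure: Structure, spec: MutationSpec,
                match_mut: bool = False) -> ResidueHandle:
    """Find the residue a mutation refers to.

    The residue must match chain, author position and insertion code, and its
    3-letter name must map to ``spec.wt`` (or ``spec.mut`` when ``match_mut``
    is set — used for hypothetical reverse records, where the structure holds
    the forward wild type).
    """
    expected = spec.mut if match_mut else spec.wt
    found = None
    for res in structure.residues():
        if (res.chain_id, res.residue_seq, res.insertion_code) == spec.site_key:
            found = res
            break
    if found is None:
        raise SiteNotFoundError(
            f"site not found: no residue {spec.position}{spec.icode} in chain "
            f"{spec.chain}")
    if found.one_letter != expected:
        raise WildTypeMismatchError(
            f"wild-type mismatch at {spec.chain}:{spec.position}{spec.icode}: "
            f"structure has {found.name} ({found.one_letter}), expected {expected} "
            "(check numbering and chain)")
    return found


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _vdw_radius(element: str) -> float:
    return _VDW.get(element.upper(), _VDW_DEFAULT)


def _canonical_coords(structure: Structure) -> np.ndarray:
    """Coordinates in a structure-derived principal-axes frame.

    The Shrake-Rupley sphere grid is fixed in space, so raw SASA would vary
    by ~1% under rotation of the input; evaluating in a canonical frame makes
    it exactly invariant to rigid-body motion (up to eigensolver noise).
    """
    x = structure.coords
    centred = x - x.mean(axis=0)
    if len(x) < 3:
        return centred
    _, vecs = np.linalg.eigh(centred.T @ centred)
    vecs = vecs[:, ::-1]  # principal axis first
    proj = centred @ vecs
    # fix axis signs by third moment (fall back to first non-tiny coordinate)
    for k in range(3):
        s = (proj[:, k] ** 3).sum()
        if abs(s) < 1e-9:
            nz = proj[np.abs(proj[:, k]) > 1e-9, k]
            s = nz[0] if len(nz) else 1.0
        if s < 0:
            proj[:, k] = -proj[:, k]
    return proj


def atom_sasa(structure: Structure, atom_indices: Sequence[int],
              probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley accessible surface area (A^2) of selected atoms in the
    context of the whole structure (computed in a canonical frame; see
    :func:`_canonical_coords`)."""
    pts = _sphere_points(n_points)
    coords = _canonical_coords(structure)
    radii = np.array([_vdw_radius(a.element) for a in structure.atoms])
    tree = structure.kdtree()
    max_r = radii.max() + probe
    out = np.empty(len(atom_indices))
    for k, i in enumerate(atom_indices):
        ri = radii[i] + probe
        sphere = coords[i] + ri * pts
        neigh = [j for j in tree.query_ball_point(structure.atoms[i].coords,
                                                  ri + max_r) if j != i]
        if neigh:
            d = np.linalg.norm(sphere[:, None, :] - coords[neigh][None, :, :], axis=2)
            buried = (d < (radii[neigh] + probe)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        out[k] = 4.0 * math.pi * ri * ri * accessible / n_points
    return out


def relative_solvent_accessibility(structure: Structure, residue: ResidueHandle,
                                   probe: float = 1.4, n_points: int = 960) -> float:
    """Residue ASA divided by the Tien et al. theoretical maximum ASA.

    May slightly exceed 1 for highly exposed conformations.
    """
    if residue.name not in MAX_ASA:
        raise ValueError(f"no max-ASA reference for residue {residue.name}")
    heavy = [i for i in residue.atom_indices if structure.atoms[i].is_heavy]
    if not heavy:
        raise ValueError("residue has no heavy atoms")
    asa = atom_sasa(structure, heavy, probe=probe, n_points=n_points).sum()
    return float(asa / MAX_ASA[residue.name])


def rsa_class(rsa: float, threshold: float = 0.30) -> str:
    """Buried/exposed split; the threshold itself counts as buried."""
    return "buried" if rsa <= threshold else "exposed"


# ---------------------------------------------------------------------------
# writing

def _atom_line(a: Atom, serial: int, coords: np.ndarray) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (f"{record}{serial:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
            f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element.upper():>2s}\n")


def write_pdb(structure: Structure, coords: Optional[np.ndarray] = None) -> str:
    """Serialize to fixed-column PDB text (single model)."""
    xyz = structure.coords if coords is None else np.asarray(coords, float)
    lines = [_atom_line(a, i + 1, xyz[i]) for i, a in enumerate(structure.atoms)]
    lines.append("END\n")
    return "".join(lines)


def write_trajectory(structure: Structure, displacements: np.ndarray,
                     amplitude: float, n_frames: int) -> str:
    """Multi-model PDB sampling a harmonic oscillation along ``displacements``.

    Frame k (k = 1..n) has coordinates x + amplitude*sin(2*pi*k/n)*d.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    disp = np.asarray(displacements, float)
    base = structure.coords
    if disp.shape != base.shape:
        raise ValueError(
            f"displacement count {disp.shape} does not match atom count {base.shape}")
    out = []
    for k in range(1, n_frames + 1):
        phase = math.sin(2.0 * math.pi * k / n_frames)
        frame = base + amplitude * phase * disp
        out.append(f"MODEL     {k:4d}\n")
        for i, a in enumerate(structure.atoms):
            out.append(_atom_line(a, i + 1, frame[i]))
        out.append("ENDMDL\n")
    out.append("END\n")
    return "".join(out)
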