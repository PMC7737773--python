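"""Wild-type interaction features: hydrophobic contacts, contact-potential
scores, substitution propensities and residue-volume descriptors.

The bundled contact potential is a synthetic hydrophobicity-derived
quasi-chemical-style matrix (see ``data/contact_potential_synthetic.csv``);
any 20x20 matrix in plain CSV or AAINDEX3 lower-triangular format can be
loaded in its place. Substitution propensities default to BLOSUM62 (via
Biopython); residue volumes are Zamyatnin's; the hydrophobicity scale is
Kyte-Doolittle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .pharmaco_signatures import assign_categories
from .structure_io import ResidueHandle, Structure

__all__ = ["ContactPotentialMatrix", "VOLUMES", "KYTE_DOOLITTLE",
           "load_contact_potential", "read_aaindex3", "default_contact_potential",
           "blosum62", "hydrophobic_contacts", "contact_potential_score",
           "substitution_features", "volume_class", "SUBSTITUTION_FEATURE_NAMES",
           "INTERACTION_FEATURE_NAMES"]

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: Zamyatnin residue volumes (A^3).
VOLUMES = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}


@dataclass(frozen=True)
class ContactPotentialMatrix:
    """Symmetric 20x20 pairwise residue contact energies."""

    values: dict  # (aa1, aa2) -> float, all 400 ordered pairs present
    source_id: str = ""

    def __post_init__(self):
        for a in AA_ORDER:
            for b in AA_ORDER:
                if (a, b) not in self.values:
                    raise ValueError(f"contact potential missing pair {a}{b}")
                if abs(self.values[(a, b)] - self.values[(b, a)]) > 1e-9:
                    raise ValueError(f"contact potential asymmetric at {a}{b}")

    def __getitem__(self, pair) -> float:
        return self.values[pair]


def load_contact_potential(path_or_text, source_id: str = "") -> ContactPotentialMatrix:
    """Read a 20x20 matrix from CSV: header row ``aa,<20 letters>``, one row
    per residue. ``#`` lines are comments."""
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = str(path_or_text)
        if "\n" not in text:
            with open(text) as fh:
                text = fh.read()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split(",")
    cols = [c.strip() for c in header[1:]]
    values = {}
    for line in lines[1:]:
        parts = line.split(",")
        row = parts[0].strip()
        for col, v in zip(cols, parts[1:]):
            values[(row, col)] = float(v)
    return ContactPotentialMatrix(values=values, source_id=source_id)


def read_aaindex3(text: str) -> ContactPotentialMatrix:
    """Parse one AAINDEX3 entry (lower-triangular ``M rows = ..., cols = ...``
    block) into a symmetric matrix."""
    lines = text.splitlines()
    accession = ""
    values: dict = {}
    rows_order = cols_order = None
    in_matrix = False
    row_i = 0
    for line in lines:
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("M "):
            parts = {}
            for p in line[2:].split(","):
                k, v = p.split("=")
                parts[k.strip()] = v.strip()
            rows_order = parts["rows"]
            cols_order = parts["cols"]
            in_matrix = True
            row_i = 0
        elif line.startswith("//"):
            in_matrix = False
        elif in_matrix:
            entries = line.split()
            if not entries:
                continue
            row_aa = rows_order[row_i]
            for j, v in enumerate(entries):
                col_aa = cols_order[j]
                val = float("nan") if v in ("-", "NA") else float(v)
                values[(row_aa, col_aa)] = val
                values[(col_aa, row_aa)] = val
            row_i += 1
    return ContactPotentialMatrix(values=values, source_id=accession)


@lru_cache(maxsize=1)
def default_contact_potential() -> ContactPotentialMatrix:
    text = resources.files("ddgdyn.data").joinpath(
        "contact_potential_synthetic.csv").read_text()
    return load_contact_potential(text, source_id="SYNTH-KD-QC")


@lru_cache(maxsize=1)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------

def hydrophobic_contacts(structure: Structure, site: ResidueHandle,
                         threshold: float = 4.5) -> int:
    """Number of hydrophobic atom contacts between the site residue and the
    rest of the structure (both atoms carrying the Hydrophobic category,
    heavy-atom distance <= threshold, closed)."""
    site_set = set(site.atom_indices)
    tree = structure.kdtree()
    count = 0
    for i in site.atom_indices:
        a = structure.atoms[i]
        if not a.is_heavy or "Hydrophobic" not in assign_categories(
                a.name, a.residue_name):
            continue
        for j in tree.query_ball_point(a.coords, threshold):
            if j in site_set:
                continue
            b = structure.atoms[j]
            if not b.is_heavy:
                continue
            if "Hydrophobic" in assign_categories(b.name, b.residue_name):
                count += 1
    return count


def _cb_coord(structure: Structure, res: ResidueHandle):
    name = "CA" if res.name == "GLY" else "CB"
    i = res.atom_index(structure, name)
    if i is None:  # fall back to CA if CB missing from the file
        i = res.atom_index(structure, "CA")
    return None if i is None else structure.atoms[i].coords


def contact_potential_score(structure: Structure, site: ResidueHandle,
                            matrix: ContactPotentialMatrix | None = None,
                            cb_cutoff: float = 8.0) -> float:
    """Sum of pair potentials between the site residue and all residues whose
    Cbeta (Calpha for GLY) lies within ``cb_cutoff`` of the site's."""
    if matrix is None:
        matrix = default_contact_potential()
    site_aa = _AA3TO1.get(site.name)
    if site_aa is None:
        raise ValueError(f"non-standard site residue {site.name}")
    origin = _cb_coord(structure, site)
    if origin is None:
        raise ValueError("site residue lacks CB/CA")
    total = 0.0
    site_key = (site.chain_id, site.residue_seq, site.insertion_code)
    for res in structure.residues():
        aa = _AA3TO1.get(res.name)
        if aa is None:
            continue
        if (res.chain_id, res.residue_seq, res.insertion_code) == site_key:
            continue
        c = _cb_coord(structure, res)
        if c is None:
            continue
        if np.linalg.norm(c - origin) <= cb_cutoff:
            total += matrix[(site_aa, aa)]
    return float(total)


SUBSTITUTION_FEATURE_NAMES = ("sub_propensity", "sub_dvolume", "sub_dhydro")


def substitution_features(wt: str, mut: str) -> np.ndarray:
    """(BLOSUM62[wt,mut], volume(mut)-volume(wt), KD(mut)-KD(wt)).

    The two difference terms are antisymmetric under swapping wt and mut.
    """
    b = blosum62()
    return np.array([float(b[wt, mut]),
                     VOLUMES[mut] - VOLUMES[wt],
                     KYTE_DOOLITTLE[mut] - KYTE_DOOLITTLE[wt]])


INTERACTION_FEATURE_NAMES = ("int_hydrophobic_contacts", "int_contact_potential")


def volume_class(wt: str, mut: str, tol: float = 25.0) -> str:
    """large_to_small / small_to_large / similar, with |dV| <= tol similar
    (inclusive)."""
    dv = VOLUMES[mut] - VOLUMES[wt]
    if abs(dv) <= tol:
        return "similar"
    return "small_to_large" if dv > 0 else "large_to_small"
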