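"""Synthetic structures and datasets.

Everything the package needs for development and testing is generated here:
ideal alpha-helices built from standard internal coordinates (NeRF chain
extension with phi=-57, psi=-47), packed atom clusters that drive relative
solvent accessibility towards zero, and regression datasets with a planted
linear signal over the real feature pipeline.

The helices carry backbone atoms (N, CA, C, O) plus a CB for every non-glycine
residue; geometry is ideal, not energy-minimized, which is sufficient to
exercise every feature extractor but is explicitly non-physical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .structure_io import (Atom, MultiMutation, MutationSpec, Structure,
                           STANDARD_AA1, parse_structure, write_pdb)

__all__ = ["SyntheticConfig", "TrainingSet", "make_helix",
           "make_packed_cluster", "make_training_set"]

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# ideal backbone internal coordinates (lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF: place atom D given A-B-C, |CD|, angle(BCD) and dihedral(ABCD)."""
    ang, dih = math.radians(angle), math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(dih),
                   bond * math.sin(ang) * math.sin(dih)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_helix(n_residues: int = 30, sequence: Optional[str] = None,
               chain: str = "A", seed: int = 0) -> tuple[Structure, str]:
    """Ideal alpha-helix with backbone + CB atoms.

    Returns the parsed :class:`Structure` and its PDB text (so that every
    fixture has gone through the real parser). Consecutive Calpha atoms come
    out ~3.8 A apart; the rise per residue is ~1.5 A with ~100 deg of twist,
    as dictated by the ideal (phi, psi) = (-57, -47).
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues for a helix fixture")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(sorted(STANDARD_AA1), size=n_residues))
    sequence = sequence.upper()
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    bad = set(sequence) - STANDARD_AA1
    if bad:
        raise ValueError(f"invalid sequence letters: {sorted(bad)}")

    # seed triad for residue 1
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(_A_N_CA_C)
    C = [CA[0] + np.array([-_B_CA_C * math.cos(ang), _B_CA_C * math.sin(ang), 0.0])]
    for i in range(1, n_residues):
        n_next = _place(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, _PSI)
        ca_next = _place(CA[-1], C[-1], n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = _place(C[-1], n_next, ca_next, _B_CA_C, _A_N_CA_C, _PHI)
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)

    atoms = []
    serial = 1
    for i in range(n_residues):
        res3 = _AA1TO3[sequence[i]]
        # carbonyl O: trans to the next N about the CA-C axis
        o = _place(N[i], CA[i], C[i], 1.231, 120.8, _PSI + 180.0)
        entries = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i]),
                   ("O", "O", o)]
        if res3 != "GLY":
            cb = _place(C[i], N[i], CA[i], 1.530, 110.5, 122.55)
            entries.append(("CB", "C", cb))
        for name, element, xyz in entries:
            atoms.append(Atom(serial=serial, name=name, element=element,
                              residue_name=res3, chain_id=chain,
                              residue_seq=i + 1, insertion_code="",
                              coords=xyz))
            serial += 1
    text = write_pdb(Structure(atoms=atoms, source_id="helix"))
    return parse_structure(text, source_id=f"helix{n_residues}"), text


def make_packed_cluster(n_shells: int = 2, seed: int = 0) -> tuple[Structure, str]:
    """A central ALA residue progressively buried by occluding carbon atoms.

    Occluders sit at 4.2 A from the residue centroid; each "shell" adds the
    next 8 points of a 64-point spherical spiral, so every added shell
    strictly decreases the central residue's solvent accessibility (RSA -> 0
    around 6-7 shells; at most 8 shells).
    """
    if not 0 <= n_shells <= 8:
        raise ValueError("n_shells must be in [0, 8]")
    helix, _ = make_helix(8, sequence="AAAAAAAA", seed=seed)
    # take residue 1's atoms, recentred at origin
    res = helix.residues()[0]
    res_atoms = [helix.atoms[i] for i in res.atom_indices]
    centroid = np.mean([a.coords for a in res_atoms], axis=0)
    atoms = []
    serial = 1
    for a in res_atoms:
        atoms.append(Atom(serial=serial, name=a.name, element=a.element,
                          residue_name="ALA", chain_id="A", residue_seq=1,
                          insertion_code="", coords=a.coords - centroid))
        serial += 1
    pts = _fibonacci_sphere(64)
    for k in range(8 * n_shells):
        atoms.append(Atom(serial=serial, name=f"C{k}", element="C",
                          residue_name="CLS", chain_id="A",
                          residue_seq=100 + k // 8, insertion_code="",
                          coords=4.2 * pts[k], is_hetero=True))
        serial += 1
    text = write_pdb(Structure(atoms=atoms, source_id="cluster"))
    return parse_structure(text, source_id=f"cluster{n_shells}"), text


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


# ---------------------------------------------------------------------------
# planted-signal regression datasets

@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for the planted-signal training-set generator.

    ddG = sum_f w_f * feature_f + Normal(0, noise_sigma). Weights are scaled
    so every planted feature contributes ``component_std`` kcal/mol of spread
    (total signal std ~ 1.1 kcal/mol with the default five features — a
    realistic span for single-mutation stability data). Non-planted feature
    columns are row-permuted so that only the planted columns carry signal,
    making "informative feature recovery" well defined despite the strong
    collinearity of signature counts.
    """

    n_residues: int = 40
    sequence: Optional[str] = None
    seed: int = 0
    n_records: int = 500
    noise_sigma: float = 0.1
    planted: tuple[str, ...] = ("rsa", "int_contact_potential",
                                "sub_dvolume", "sub_dhydro", "dyn_fluct")
    component_std: float = 0.5
    permute_uninformative: bool = True


@dataclass
class TrainingSet:
    records: list  # StabilityRecord
    X: pd.DataFrame
    y: np.ndarray
    weights: dict[str, float]
    intercept: float
    structure: Structure
    config: SyntheticConfig


def make_training_set(config: SyntheticConfig = SyntheticConfig()) -> TrainingSet:
    """Sample single mutations on a helix fixture and plant a linear ddG."""
    from .dataset import StabilityRecord
    from .model import Featurizer

    rng = np.random.default_rng(config.seed)
    structure, _ = make_helix(config.n_residues, sequence=config.sequence,
                              seed=config.seed)
    feat = Featurizer()
    residues = [r for r in structure.residues()
                if r.one_letter is not None][2:-2]  # skip frayed termini
    combos = []
    for res in residues:
        for mut in sorted(STANDARD_AA1 - {res.one_letter}):
            combos.append(MutationSpec(chain=res.chain_id, wt=res.one_letter,
                                       position=res.residue_seq, mut=mut))
    idx = rng.integers(0, len(combos), size=config.n_records)
    specs = [combos[i] for i in idx]

    cache: dict[str, pd.Series] = {}
    rows = []
    for spec in specs:
        key = str(spec)
        if key not in cache:
            cache[key] = feat.featurize_single(structure, spec)
        rows.append(cache[key])
    X = pd.DataFrame(rows).reset_index(drop=True)

    missing = [f for f in config.planted if f not in X.columns]
    if missing:
        raise ValueError(f"planted features not in feature set: {missing}")
    weights = {}
    sign = 1.0
    for name in config.planted:
        std = float(X[name].std(ddof=0))
        if std == 0.0:
            raise ValueError(f"planted feature {name} has zero variance")
        weights[name] = sign * config.component_std / std
        sign = -sign
    # centred contributions: ddG deviates around a zero baseline, so both
    # stabilizing and destabilizing classes are populated
    intercept = -sum(w * float(X[f].mean()) for f, w in weights.items())
    y_signal = intercept + sum(w * X[f].to_numpy() for f, w in weights.items())
    y = y_signal + rng.normal(0.0, config.noise_sigma, size=len(X))

    if config.permute_uninformative:
        for col in X.columns:
            if col not in config.planted:
                X[col] = rng.permutation(X[col].to_numpy())

    records = [StabilityRecord(structure_ref=structure.source_id,
                               mutation=MultiMutation(specs=(spec,)),
                               ddg=float(y[i]), is_reverse=False,
                               group_key=structure.source_id)
               for i, spec in enumerate(specs)]
    return TrainingSet(records=records, X=X, y=np.asarray(y, float),
                       weights=weights, intercept=float(intercept),
                       structure=structure, config=config)
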