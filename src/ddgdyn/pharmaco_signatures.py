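"""Pharmacophore atom typing and graph-based cutoff-scanning signatures.

Each heavy atom of the 20 standard residues is assigned one or more of eight
pharmacophore categories from a bundled, human-readable table. The signature
of a mutation site is the cumulative count, per unordered category pair, of
atom pairs in the wild-type residue environment closer than each of an
ascending set of distance thresholds — i.e. a family of cumulative
distribution functions of category-pair distances.

The environment deliberately excludes the mutated residue's own side chain
(backbone retained): it describes what surrounds the residue being replaced,
and is therefore identical for a forward mutation and its hypothetical
reverse.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from itertools import combinations_with_replacement, product

import numpy as np

from .structure_io import (Atom, BACKBONE_NAMES, ResidueHandle, Structure)

__all__ = ["CATEGORIES", "PAIRS", "DEFAULT_RADIUS", "DEFAULT_THRESHOLDS",
           "Environment", "SignatureVector", "assign_categories",
           "build_environment", "compute_signature", "flatten",
           "signature_feature_names"]

logger = logging.getLogger(__name__)

#: The fixed, ordered pharmacophore category set.
CATEGORIES: tuple[str, ...] = ("Hydrophobic", "Positive", "Negative",
                               "HBondAcceptor", "HBondDonor", "Aromatic",
                               "Sulfur", "Neutral")
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}

#: Unordered category pairs (incl. self-pairs), lexicographic in CATEGORIES
#: order — 36 pairs.
PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(CATEGORIES, 2))
_PAIR_INDEX = {p: i for i, p in enumerate(PAIRS)}

DEFAULT_RADIUS = 10.0  # A around the site Calpha
DEFAULT_THRESHOLDS = (3.0, 4.5, 6.0, 7.5, 9.0, 10.0)  # A, ascending


def _load_table() -> dict[tuple[str, str], frozenset]:
    table = {}
    text = resources.files("ddgdyn.data").joinpath("pharmacophores.tsv").read_text()
    reader = csv.reader((l for l in text.splitlines()
                         if l and not l.startswith("#")), delimiter="\t")
    header = next(reader)
    assert header == ["residue", "atom", "categories"]
    for res, atom, cats in reader:
        catset = frozenset(cats.split(";"))
        unknown = catset - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in table: {unknown}")
        table[(res, atom)] = catset
    return table


_TABLE = _load_table()
_NEUTRAL = frozenset({"Neutral"})
_warned: set[tuple[str, str]] = set()


def assign_categories(atom_name: str, residue_name: str) -> frozenset:
    """Pharmacophore categories of a (residue, atom) pair.

    Unknown combinations fall back to Neutral with a single logged warning.
    """
    key = (residue_name, atom_name)
    cats = _TABLE.get(key)
    if cats is None:
        if key not in _warned:
            logger.warning("no pharmacophore entry for %s/%s; using Neutral",
                           residue_name, atom_name)
            _warned.add(key)
        return _NEUTRAL
    return cats


@dataclass
class Environment:
    """Heavy atoms (with categories) within ``radius`` of a site's Calpha,
    excluding the site's own side chain."""

    center: np.ndarray
    radius: float
    atoms: list[Atom]
    categories: list[frozenset]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class SignatureVector:
    thresholds: tuple[float, ...]
    counts: np.ndarray  # (36, n_thresholds) int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        assert self.counts.shape == (len(PAIRS), len(self.thresholds))


def build_environment(structure: Structure, site: ResidueHandle,
                      radius: float = DEFAULT_RADIUS) -> Environment:
    """Collect the wild-type residue environment around the site Calpha.

    Closed ball (distance <= radius); heavy atoms only; the site's side-chain
    atoms are excluded, its backbone kept.
    """
    ca = site.atom_index(structure, "CA")
    if ca is None:
        raise ValueError(f"site {site.chain_id}:{site.residue_seq} has no CA atom")
    center = structure.atoms[ca].coords
    site_side = {i for i in site.atom_indices
                 if structure.atoms[i].name not in BACKBONE_NAMES}
    atoms, cats = [], []
    idx = structure.kdtree().query_ball_point(center, radius)
    for i in sorted(idx):
        a = structure.atoms[i]
        if not a.is_heavy or i in site_side:
            continue
        if np.linalg.norm(a.coords - center) > radius:  # guard fp edge
            continue
        atoms.append(a)
        cats.append(assign_categories(a.name, a.residue_name))
    if not atoms:
        raise ValueError("empty environment (degenerate structure)")
    return Environment(center=center, radius=radius, atoms=atoms,
                       categories=cats)


def compute_signature(env: Environment,
                      thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
                      ) -> SignatureVector:
    """Cumulative category-pair contact counts at each distance threshold.

    For every unordered atom pair (i<j) and every category a of atom i and b
    of atom j, count[{a,b}][t] is incremented for each threshold t >= d(i,j).
    Counts are therefore non-decreasing along the threshold axis.
    """
    thr = tuple(float(t) for t in thresholds)
    if any(t2 <= t1 for t1, t2 in zip(thr, thr[1:])):
        raise ValueError("thresholds must be strictly ascending")
    counts = np.zeros((len(PAIRS), len(thr)), dtype=np.int64)
    if len(env) >= 2:
        coords = np.array([a.coords for a in env.atoms])
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        tmax = thr[-1]
        n = len(env)
        thr_arr = np.asarray(thr)
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] > tmax:
                    continue
                first = int(np.searchsorted(thr_arr, d[i, j]))
                for a, b in product(env.categories[i], env.categories[j]):
                    pair = (a, b) if _CAT_INDEX[a] <= _CAT_INDEX[b] else (b, a)
                    counts[_PAIR_INDEX[pair], first:] += 1
    return SignatureVector(thresholds=thr, counts=counts)


def flatten(sig: SignatureVector) -> np.ndarray:
    """Deterministic flat ordering: pairs in lexicographic category order,
    thresholds ascending within each pair."""
    return sig.counts.reshape(-1).astype(float)


def signature_feature_names(thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
                            ) -> list[str]:
    return [f"sig_{a}|{b}@{t:g}" for a, b in PAIRS for t in thresholds]
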