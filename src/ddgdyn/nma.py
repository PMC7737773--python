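"""Coarse-grained elastic-network normal mode analysis.

A Calpha-only elastic network with uniform masses: either the anisotropic
network model (``anm``; unit springs between all Calpha pairs within a cutoff,
default 15 A) or a Hinsen-style distance-dependent force field (``calpha``;
k(r) = a*r - b for r < 4 A, c*r^-6 beyond, springs between all pairs).
Modes come from the symmetric eigendecomposition of the 3N x 3N Hessian; a
connected, non-collinear network has exactly six zero modes (rigid
translations and rotations). The absolute spring-constant scale is arbitrary
and cancels in every normalized quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx
import numpy as np
import scipy.linalg

from .structure_io import Structure

__all__ = ["ElasticNetwork", "ModeSet", "DynamicsProfile", "FORCE_FIELDS",
           "build_network", "compute_modes", "fluctuations",
           "correlation_matrix", "porcupine", "dynamics_profile",
           "site_dynamics_features", "DYNAMICS_FEATURE_NAMES"]

TRIVIAL_TOL = 1e-8  # lambda < tol * lambda_max counts as a rigid-body mode

# Hinsen calpha force-field constants (r in Angstrom; scale arbitrary)
_HINSEN_A, _HINSEN_B, _HINSEN_C = 8.6e2, 2.39e3, 1.28e8


def _anm_spring(r: float, cutoff: float) -> float:
    return 1.0 if r <= cutoff else 0.0


def _calpha_spring(r: float, cutoff: float) -> float:
    if r < 4.0:
        k = _HINSEN_A * r - _HINSEN_B
        if k <= 0.0:
            raise ValueError(f"calpha force field undefined at r={r:.2f} A "
                             "(overlapping Calpha atoms)")
        return k
    return _HINSEN_C * r ** -6


FORCE_FIELDS: dict[str, Callable[[float, float], float]] = {
    "anm": _anm_spring,
    "calpha": _calpha_spring,
}


@dataclass
class ElasticNetwork:
    nodes: np.ndarray  # (N, 3) Calpha coordinates, A
    springs: list[tuple[int, int, float]]  # (i, j, k) with i < j
    force_field: str
    cutoff: Optional[float] = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class ModeSet:
    eigenvalues: np.ndarray  # ascending, length 3N
    eigenvectors: np.ndarray  # (3N, 3N), columns orthonormal
    n_trivial: int
    n_nodes: int


@dataclass
class DynamicsProfile:
    fluctuation: np.ndarray  # (N,) mean-square fluctuation, arbitrary units
    correlation: np.ndarray  # (N, N) in [-1, 1], unit diagonal
    porcupine: np.ndarray  # (N, 3) first non-trivial mode, max norm 1
    n_trivial: int


def build_network(structure: Structure, force_field: str = "anm",
                  cutoff: float = 15.0) -> ElasticNetwork:
    """Build the Calpha elastic network for a structure.

    Raises if the network is disconnected (names the smallest component) or
    has fewer than three Calpha atoms.
    """
    if force_field not in FORCE_FIELDS:
        raise ValueError(f"unknown force field {force_field!r}; "
                         f"available: {sorted(FORCE_FIELDS)}")
    ca = structure.ca_indices()
    if len(ca) < 3:
        raise ValueError(f"need >= 3 Calpha atoms, found {len(ca)}")
    nodes = np.array([structure.atoms[i].coords for i in ca])
    return network_from_coords(nodes, force_field=force_field, cutoff=cutoff)


def network_from_coords(nodes: np.ndarray, force_field: str = "anm",
                        cutoff: float = 15.0) -> ElasticNetwork:
    """Elastic network directly from an (N, 3) coordinate array."""
    nodes = np.asarray(nodes, float)
    spring_fn = FORCE_FIELDS[force_field]
    n = len(nodes)
    springs = []
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(nodes[j] - nodes[i]))
            k = spring_fn(r, cutoff)
            if k > 0.0:
                springs.append((i, j, k))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, _ in springs)
    comps = sorted(nx.connected_components(g), key=len)
    if len(comps) > 1:
        raise ValueError(
            f"elastic network is disconnected ({len(comps)} components; "
            f"smallest has nodes {sorted(comps[0])})")
    return ElasticNetwork(nodes=nodes, springs=springs,
                          force_field=force_field, cutoff=cutoff)


def hessian(net: ElasticNetwork) -> np.ndarray:
    """Assemble the 3N x 3N ENM Hessian from pairwise spring super-elements."""
    n = net.n_nodes
    h = np.zeros((3 * n, 3 * n))
    for i, j, k in net.springs:
        d = net.nodes[j] - net.nodes[i]
        r2 = float(d @ d)
        block = -(k / r2) * np.outer(d, d)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return h


def compute_modes(net: ElasticNetwork) -> ModeSet:
    """Symmetric eigendecomposition of the network Hessian.

    Eigenvalues ascending; the count of near-zero modes (lambda < 1e-8 *
    lambda_max) is checked — more than six signals an ill-conditioned network.
    """
    h = hessian(net)
    evals, evecs = scipy.linalg.eigh(h)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise ValueError("degenerate network: no positive eigenvalues")
    tol = TRIVIAL_TOL * lam_max
    n_trivial = int(np.sum(evals < tol))
    if n_trivial > 6:
        raise ValueError(
            f"ill-conditioned network: {n_trivial} near-zero eigenvalues")
    evals = np.where(np.abs(evals) < tol, np.maximum(evals, 0.0), evals)
    return ModeSet(eigenvalues=evals, eigenvectors=evecs,
                   n_trivial=n_trivial, n_nodes=net.n_nodes)


def fluctuations(modes: ModeSet) -> np.ndarray:
    """Per-node mean-square fluctuation: f_i = sum_m (1/lambda_m) |v_m,i|^2
    over non-trivial modes (arbitrary units)."""
    lam = modes.eigenvalues[modes.n_trivial:]
    v = modes.eigenvectors[:, modes.n_trivial:]
    per_dof = (v * v) / lam[None, :]
    return per_dof.sum(axis=1).reshape(modes.n_nodes, 3).sum(axis=1)


def correlation_matrix(modes: ModeSet) -> np.ndarray:
    """Normalized residue cross-correlation: C_ij = cov_ij / sqrt(cov_ii cov_jj)
    with cov_ij = sum_m v_m,i . v_m,j / lambda_m over non-trivial modes."""
    lam = modes.eigenvalues[modes.n_trivial:]
    v = modes.eigenvectors[:, modes.n_trivial:]
    n = modes.n_nodes
    vi = v.reshape(n, 3, -1)
    cov = np.einsum("iam,jam->ij", vi / lam[None, None, :], vi)
    d = np.sqrt(np.diag(cov))
    c = cov / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return np.clip((c + c.T) / 2.0, -1.0, 1.0)


def porcupine(modes: ModeSet, mode_index: int) -> np.ndarray:
    """Displacement field of one mode as (N, 3) vectors scaled to max norm 1.

    ``mode_index`` is 1-based over the ascending spectrum and must address a
    non-trivial mode (> n_trivial).
    """
    if mode_index <= modes.n_trivial:
        raise ValueError(
            f"mode {mode_index} is a trivial rigid-body mode "
            f"(first non-trivial is {modes.n_trivial + 1})")
    if mode_index > len(modes.eigenvalues):
        raise ValueError(f"mode {mode_index} out of range")
    vec = modes.eigenvectors[:, mode_index - 1].reshape(modes.n_nodes, 3)
    norms = np.linalg.norm(vec, axis=1)
    return vec / norms.max()


def dynamics_profile(modes: ModeSet) -> DynamicsProfile:
    return DynamicsProfile(
        fluctuation=fluctuations(modes),
        correlation=correlation_matrix(modes),
        porcupine=porcupine(modes, modes.n_trivial + 1),
        n_trivial=modes.n_trivial,
    )


#: Documented order of the per-site dynamics features.
DYNAMICS_FEATURE_NAMES = ("dyn_fluct", "dyn_fluct_pct", "dyn_mean_abs_corr",
                          "dyn_mode1_norm")


def site_dynamics_features(profile: DynamicsProfile, site: int) -> np.ndarray:
    """Four per-site dynamics features, in DYNAMICS_FEATURE_NAMES order:
    fluctuation, fluctuation rank percentile (max -> 1.0), mean absolute
    correlation of the site's row, and the site's displacement norm in the
    first non-trivial mode (after max-norm scaling)."""
    f = profile.fluctuation
    if not 0 <= site < len(f):
        raise IndexError(f"site index {site} out of range")
    pct = float(np.sum(f <= f[site]) / len(f))
    return np.array([
        float(f[site]),
        pct,
        float(np.mean(np.abs(profile.correlation[site]))),
        float(np.linalg.norm(profile.porcupine[site])),
    ])
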