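"""Anisotropic network model (ANM) of backbone vibration.

Builds the standard ANM Hessian from alpha-carbon contacts within a
distance cutoff, eigendecomposes it, and derives two per-residue profiles:

- *mean effective stiffness*: for each residue pair, the effective force
  constant of the network's response along the inter-residue direction
  (inverse of the mode-sum compliance), averaged over all partners;
- *mean-square fluctuations*: the trace of each residue's 3x3 diagonal
  block of the pseudo-inverse Hessian, an RMSF surrogate when molecular
  dynamics profiles are not supplied.

A connected network has exactly six rigid-body zero modes; geometries
that produce more (e.g. collinear bead chains) are rejected where the
derived quantities would be meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["ANMModel", "build_anm", "stiffness_profile",
           "fluctuation_profile"]

_ZERO_MODE_RTOL = 1e-8


@dataclass
class ANMModel:
    coords: np.ndarray          # (N, 3)
    cutoff: float
    gamma: float
    hessian: np.ndarray         # (3N, 3N)
    eigenvalues: np.ndarray     # ascending
    eigenvectors: np.ndarray    # columns
    n_zero_modes: int

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


def _connected(adjacency: np.ndarray) -> bool:
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adjacency[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def _components(adjacency: np.ndarray):
    n = adjacency.shape[0]
    label = -np.ones(n, dtype=int)
    comp = 0
    for start in range(n):
        if label[start] >= 0:
            continue
        stack = [start]
        label[start] = comp
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adjacency[i]):
                if label[j] < 0:
                    label[j] = comp
                    stack.append(j)
        comp += 1
    return [np.flatnonzero(label == c).tolist() for c in range(comp)]


def build_anm(coords, cutoff: float = 15.0, gamma: float = 1.0) -> ANMModel:
    """Build and diagonalize the ANM Hessian from Calpha coordinates.

    Contacts are residue pairs within ``cutoff`` angstroms; each contributes
    a spring of stiffness ``gamma`` acting along the inter-residue vector.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 residues")
    if not np.all(np.isfinite(x)):
        raise ValueError("coordinates must be finite")
    dist = squareform(pdist(x))
    adjacency = (dist > 0) & (dist <= cutoff)
    if not _connected(adjacency):
        comps = _components(adjacency)
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} A: "
            f"{len(comps)} components with sizes "
            f"{sorted(len(c) for c in comps)}")
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(adjacency, k=1))
    for i, j in zip(ii, jj):
        d = x[j] - x[i]
        block = -gamma * np.outer(d, d) / (d @ d)
        hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    evals, evecs = np.linalg.eigh(hessian)
    n_zero = int(np.sum(np.abs(evals) < _ZERO_MODE_RTOL
                        * max(1.0, float(evals[-1]))))
    return ANMModel(coords=x, cutoff=float(cutoff), gamma=float(gamma),
                    hessian=hessian, eigenvalues=evals, eigenvectors=evecs,
                    n_zero_modes=n_zero)


def _pseudo_inverse(anm: ANMModel) -> np.ndarray:
    if anm.n_zero_modes != 6:
        raise ValueError(
            f"expected 6 rigid-body zero modes, found {anm.n_zero_modes}; "
            "degenerate (e.g. collinear) geometry is not supported")
    lam = anm.eigenvalues[anm.n_zero_modes:]
    vec = anm.eigenvectors[:, anm.n_zero_modes:]
    return (vec / lam) @ vec.T


def stiffness_profile(anm: ANMModel) -> np.ndarray:
    """Per-residue mean effective stiffness from the ANM mode sum.

    For each pair (i, j), the compliance along the unit inter-residue
    vector e_ij is e^T (C_ii + C_jj - C_ij - C_ji) e with C the
    pseudo-inverse Hessian; the pair's effective force constant is its
    reciprocal, and residues receive the mean over all partners.
    """
    cov = _pseudo_inverse(anm)
    n = anm.n_residues
    x = anm.coords
    kappa = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = x[j] - x[i]
            e = d / np.linalg.norm(d)
            cii = cov[3 * i:3 * i + 3, 3 * i:3 * i + 3]
            cjj = cov[3 * j:3 * j + 3, 3 * j:3 * j + 3]
            cij = cov[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            compliance = e @ (cii + cjj - cij - cij.T) @ e
            kappa[i, j] = kappa[j, i] = 1.0 / compliance
    return kappa.sum(axis=1) / (n - 1)


def fluctuation_profile(anm: ANMModel, normalize: bool = True) -> np.ndarray:
    """Per-residue mean-square fluctuation (RMSF surrogate).

    The trace of each residue's 3x3 diagonal block of the pseudo-inverse
    Hessian; normalized to mean 1 when ``normalize``.
    """
    cov = _pseudo_inverse(anm)
    diag = np.diag(cov)
    msf = diag.reshape(-1, 3).sum(axis=1)
    if normalize:
        msf = msf / msf.mean()
    return msf
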