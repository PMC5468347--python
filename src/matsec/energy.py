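"""Interaction-energy features ("folding components").

The estimated total pairwise interaction energy of a polypeptide, per
residue, is the quadratic form

    E/L = n' P n

where ``n`` is the 20-vector of residue frequencies and ``P`` a symmetric
20x20 energy predictor matrix (arbitrary energy units) whose element P_ij
says how the energy of residue type i depends on the occurrence of type j.
Eigendecomposition of P splits folding into principal components: we call
the eigenvectors folding components (FCs).  Each sequence contributes one
feature per component,

    e_k = sign(lambda_k) * (V_k . n),

emitted as ``fc:e1`` .. ``fc:e20`` in decreasing-eigenvalue order.  Note
e_k is the projection-based quantity as defined, not the exact quadratic
energy contribution lambda_k (V_k . n)^2, which is exposed separately as a
diagnostic (:meth:`EnergyFeatures.quadratic`).

Conventions making the decomposition reproducible: components are ordered
by decreasing eigenvalue (ties broken by the first differing eigenvector
coordinate after sign fixing) and each eigenvector is sign-fixed so that
its largest-magnitude coordinate is positive.

The bundled default matrix (``data/energy_matrix_synthetic.txt``) is a
synthetic stand-in built from a hydrophobicity outer product plus an
electrostatic term and seeded noise; any symmetric 20x20 matrix file can be
supplied in its place.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .seqio import AA20, AA20_SET

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclass
class CompositionVector:
    """Residue frequencies n_i = N_i / L in AA20 order."""

    n: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.float64)
        if self.n.shape != (20,):
            raise ValueError("composition must be a 20-vector")
        if (self.n < -1e-12).any():
            raise ValueError("negative composition entry")


def composition(seq: str) -> CompositionVector:
    """Composition over standard residues; gaps and X/B/Z/U/O are excluded
    from both numerator and denominator."""
    counts = np.zeros(20)
    for c in seq:
        if c in AA20_SET:
            counts[_AA_INDEX[c]] += 1
    L = counts.sum()
    if L == 0:
        raise ValueError("no standard residues in sequence")
    return CompositionVector(counts / L)


@dataclass
class EnergyModel:
    """Symmetric predictor matrix P with its ordered, sign-fixed spectrum."""

    P: np.ndarray
    eigenvalues: np.ndarray  # decreasing
    eigenvectors: np.ndarray  # columns V_k, orthonormal

    def __post_init__(self) -> None:
        recon = (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T
        if not np.allclose(recon, self.P, atol=1e-8):
            raise ValueError("spectral reconstruction failed")
        if not np.allclose(self.eigenvectors.T @ self.eigenvectors, np.eye(20), atol=1e-8):
            raise ValueError("eigenvectors not orthonormal")


def decompose(P: np.ndarray) -> EnergyModel:
    """Eigendecompose a symmetric 20x20 matrix under the package conventions."""
    P = np.asarray(P, dtype=np.float64)
    if P.shape != (20, 20):
        raise ValueError(f"expected a 20x20 matrix, got {P.shape}")
    lam, V = np.linalg.eigh(P)
    order = np.argsort(-lam, kind="stable")
    lam, V = lam[order], V[:, order]
    for k in range(20):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    # degenerate eigenvalues: stable order by first differing coordinate
    k = 0
    while k < 20:
        m = k + 1
        while m < 20 and np.isclose(lam[m], lam[k], rtol=0, atol=1e-12):
            m += 1
        if m - k > 1:
            block = V[:, k:m]
            idx = np.lexsort(block[::-1])
            V[:, k:m] = block[:, idx]
        k = m
    return EnergyModel(P=P, eigenvalues=lam, eigenvectors=V)


def load_energy_matrix(path) -> EnergyModel:
    """Read a whitespace-delimited energy matrix file.

    Format: optional '#' comment lines, then a header row of 20 one-letter
    residue codes giving the row/column order, then 20 rows of 20 numbers.
    The matrix is reordered to canonical AA20 order; asymmetries below 1e-6
    are averaged away, larger ones are an error.
    """
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split()
                continue
            rows.append([float(x) for x in line.split()])
    if header is None or sorted(header) != sorted(AA20):
        raise ValueError(f"{path}: header must list the 20 one-letter residue codes")
    P = np.array(rows, dtype=np.float64)
    if P.shape != (20, 20):
        raise ValueError(f"{path}: expected 20x20 values, got {P.shape}")
    asym = np.abs(P - P.T).max()
    if asym >= 1e-6:
        raise ValueError(f"{path}: matrix is asymmetric (max |P-P'| = {asym:g})")
    P = (P + P.T) / 2.0
    # reorder into canonical residue order
    perm = [header.index(a) for a in AA20]
    P = P[np.ix_(perm, perm)]
    return decompose(P)


def default_energy_model() -> EnergyModel:
    """The bundled synthetic 20x20 predictor matrix."""
    ref = resources.files("matsec.data") / "energy_matrix_synthetic.txt"
    with resources.as_file(ref) as path:
        return load_energy_matrix(path)


def interaction_energy(n: CompositionVector, model: EnergyModel) -> float:
    """Estimated total interaction energy per residue, n' P n."""
    return float(n.n @ model.P @ n.n)


@dataclass
class EnergyFeatures:
    """Per-component energies e_k plus the total quadratic energy E/L."""

    e: np.ndarray
    total: float
    _projections: np.ndarray = None
    _eigenvalues: np.ndarray = None

    def quadratic(self) -> np.ndarray:
        """Exact per-component contributions lambda_k (V_k . n)^2 (diagnostic)."""
        return self._eigenvalues * self._projections**2


def folding_energies(n: CompositionVector, model: EnergyModel) -> EnergyFeatures:
    """e_k = sign(lambda_k) * (V_k . n); sign(0) is taken as +1 so that a
    zero eigenvalue does not annihilate the projection."""
    # per-component dot products (projection of the composition on each FC)
    proj = np.array([model.eigenvectors[:, k] @ n.n for k in range(20)])
    signs = np.where(model.eigenvalues < 0, -1.0, 1.0)
    return EnergyFeatures(
        e=signs * proj,
        total=interaction_energy(n, model),
        _projections=proj,
        _eigenvalues=model.eigenvalues,
    )
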