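"""Spectral decomposition of the marker matrix and estimators in that basis.

With X = U S V', the regression y = X beta + eps rotates to d = S b + eps~,
where d = U'y and b = V'beta.  Only the first r = rank(X) entries of b are
identified; the marker effects are recovered as beta = V1 b.  Least-squares
and ridge solutions become elementwise operations on the singular values,
which makes the noise amplification of small singular values explicit:
d_i/s_i = b_i + eps~_i/s_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SVDBasis",
    "decompose",
    "forward_transform",
    "recover_beta",
    "ols_coefficients",
    "ridge_coefficients",
    "weighting_factors",
]


@dataclass
class SVDBasis:
    """Rank-truncated SVD of the n x p genotype matrix.

    U is n x r with orthonormal columns, ``s`` the r positive singular
    values in descending order, V1 the matching p x r right-singular block.
    """

    U: np.ndarray
    s: np.ndarray
    V1: np.ndarray
    r: int
    trunc_tol: float

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.V1 = np.asarray(self.V1, dtype=float)
        if self.s.ndim != 1 or self.s.shape[0] != self.r:
            raise ValueError("s must hold exactly r singular values")
        if np.any(self.s <= 0):
            raise ValueError("singular values must be strictly positive")
        if np.any(np.diff(self.s) > 0):
            raise ValueError("singular values must be sorted in descending order")
        if self.U.shape[1] != self.r or self.V1.shape[1] != self.r:
            raise ValueError("U and V1 must each have r columns")

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def p(self) -> int:
        return self.V1.shape[0]


def decompose(X: np.ndarray, trunc_tol: float = 1e-10) -> SVDBasis:
    """SVD of X keeping singular values above ``trunc_tol`` * s1.

    Signs are fixed so the largest-magnitude entry of each column of V1 is
    positive; predictions are invariant to this choice, but it makes the
    decomposition deterministic across LAPACK implementations.
    """
    X = np.asarray(X, dtype=float)
    if not (0 <= trunc_tol < 1):
        raise ValueError("trunc_tol must lie in [0, 1)")
    if not np.all(np.isfinite(X)):
        raise ValueError("marker matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("all-zero marker matrix has no positive singular value")
    r = int(np.sum(s > trunc_tol * s[0]))
    if r == 0:
        raise ValueError("truncation removed every singular value")
    U, s, V1 = U[:, :r], s[:r], Vt[:r, :].T
    # Deterministic sign convention on V1 columns (U follows to keep X = U S V1').
    flip = np.sign(V1[np.abs(V1).argmax(axis=0), np.arange(r)])
    flip[flip == 0] = 1.0
    return SVDBasis(U=U * flip, s=s, V1=V1 * flip, r=r, trunc_tol=float(trunc_tol))


def forward_transform(basis: SVDBasis, y: np.ndarray) -> np.ndarray:
    """Rotate phenotypes into the spectral basis: d = U'y."""
    y = np.asarray(y, dtype=float)
    if y.shape != (basis.n,):
        raise ValueError(f"y must have length {basis.n}, got {y.shape}")
    return basis.U.T @ y


def recover_beta(basis: SVDBasis, b: np.ndarray) -> np.ndarray:
    """Back-transform spectral coefficients to marker effects: beta = V1 b."""
    b = np.asarray(b, dtype=float)
    if b.shape != (basis.r,):
        raise ValueError(f"b must have length {basis.r}, got {b.shape}")
    return basis.V1 @ b


def ols_coefficients(basis: SVDBasis, d: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares coefficients b*_i = d_i / s_i.

    The variance of b*_i scales as 1/s_i^2, so trailing coefficients are
    dominated by amplified noise — the motivation for spectral shrinkage.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (basis.r,):
        raise ValueError(f"d must have length {basis.r}, got {d.shape}")
    return d / basis.s


def ridge_coefficients(basis: SVDBasis, d: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Spectral ridge estimate b_i = s_i d_i / (s_i^2 + gamma_i).

    With a constant gamma = kappa this equals the dense ridge solution
    V1 (X'X + kappa I)^-1 X'y expressed in the spectral basis.
    """
    d = np.asarray(d, dtype=float)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (basis.r,))
    if d.shape != (basis.r,):
        raise ValueError(f"d must have length {basis.r}, got {d.shape}")
    if np.any(gamma < 0):
        raise ValueError("ridge parameters must be non-negative")
    return basis.s * d / (basis.s**2 + gamma)


def weighting_factors(s: np.ndarray, lam: np.ndarray, sigma2_e: float) -> np.ndarray:
    """Shrinkage weights f_i = lam_i s_i^2 / (lam_i s_i^2 + sigma2_e).

    f_i multiplies the least-squares estimate b*_i to give the conditional
    posterior mean of b_i; it lies in (0, 1), approaching 1 when the prior
    variance or signal dominates and 0 when the error variance dominates.
    """
    s = np.asarray(s, dtype=float)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), s.shape)
    if np.any(lam <= 0):
        raise ValueError("prior variances must be strictly positive")
    if not sigma2_e > 0:
        raise ValueError("error variance must be strictly positive")
    signal = lam * s**2
    return signal / (signal + sigma2_e)
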