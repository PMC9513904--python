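"""SNP-BLUP mixed-model solver.

Independent route to SNP effects and their prediction-error covariance:
fits markers directly as random regressions, so the C^gg block of the
inverted coefficient matrix IS the SNP PEC. Serves as ground truth for the
GBLUP backsolve chain in the unblended, fully genotyped limit where the
two models are exactly equivalent (G = ZZ'/k with sigma_a^2 = sigma_u^2/k).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

__all__ = ["solve_snpblup", "acc_ip_oracle", "SnpBlup"]


def solve_snpblup(
    y: np.ndarray,
    X: np.ndarray,
    Z_star: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve [[X'X, X'Z*], [Z*'X, Z*'Z* + I lambda_a]] in lambda form.

    Returns (beta_hat, a_hat, C_gg) with C_gg the marker block of the
    inverse rescaled by sigma_e^2 (the SNP PEC).
    """
    lam = sigma2_e / sigma2_a
    nf = X.shape[1]
    m = Z_star.shape[1]
    LHS = np.block(
        [[X.T @ X, X.T @ Z_star], [Z_star.T @ X, Z_star.T @ Z_star + lam * np.eye(m)]]
    )
    RHS = np.concatenate([X.T @ y, Z_star.T @ y])
    try:
        c = cho_factor(LHS)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular SNP-BLUP coefficient matrix") from err
    sol = cho_solve(c, RHS)
    C = cho_solve(c, np.eye(LHS.shape[0])) * sigma2_e
    C_gg = 0.5 * (C[nf:, nf:] + C[nf:, nf:].T)
    return sol[:nf], sol[nf:], C_gg


def acc_ip_oracle(z_j: np.ndarray, C_gg: np.ndarray, sigma2_u: float) -> float:
    """sqrt(1 - z C^gg z' / sigma_u^2), floored at 0."""
    pev = float(z_j @ C_gg @ z_j)
    return float(np.sqrt(max(0.0, 1.0 - pev / sigma2_u)))


class SnpBlup(BaseEstimator):
    """Random-regression marker model (test instrument).

    Applies to the pure-genomic case: every phenotyped animal genotyped,
    regressors the centered genotypes of the phenotyped animals.
    """

    def __init__(self, sigma2_a: float = 1.0, sigma2_e: float = 1.0) -> None:
        self.sigma2_a = sigma2_a
        self.sigma2_e = sigma2_e

    def fit(self, y: np.ndarray, X: np.ndarray, Z_star: np.ndarray) -> "SnpBlup":
        self.beta_hat_, self.a_hat_, self.C_gg_ = solve_snpblup(
            y, X, Z_star, self.sigma2_a, self.sigma2_e
        )
        return self

    def predict(self, Z_target: np.ndarray) -> np.ndarray:
        return np.asarray(Z_target, float) @ self.a_hat_

    def accuracy(self, Z_target: np.ndarray, sigma2_u: float) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z_target, float))
        pev = np.einsum("ij,jk,ik->i", Z, self.C_gg_, Z)
        return np.sqrt(np.clip(1.0 - pev / sigma2_u, 0.0, None))
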