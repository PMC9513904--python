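"""Single-step GBLUP engine.

Assembles H^-1 and the mixed-model equations for the single-trait animal
model y = Xb + Wu + e with a contemporary-group fixed effect, solves them,
and extracts prediction-error (co)variances and per-animal accuracies.

The equations are kept in lambda form (both sides divided by sigma_e^2),
which leaves the solutions unchanged; the stored inverse of the coefficient
matrix is rescaled by sigma_e^2 so that prediction-error variances are on
the usual trait-variance scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .genomic import AlleleFrequencySet, GenotypeMatrix, GrmBundle, build_grm
from .pedigree import Pedigree, relationship_matrices

__all__ = [
    "VarianceComponents",
    "build_H_inverse",
    "assemble_mme",
    "solve_mme",
    "invert_lhs",
    "acc_gebv",
    "SingleStepGBLUP",
]


@dataclass
class VarianceComponents:
    """Additive and residual variances (trait units squared)."""

    sigma2_u: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_u <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be strictly positive")

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_u


def build_H_inverse(
    A_inv: np.ndarray,
    A22_inv: np.ndarray,
    G_inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> np.ndarray:
    """H^-1 = A^-1 with (G^-1 - A22^-1) added into the genotyped block."""
    if G_inv.shape != A22_inv.shape:
        raise ValueError(f"G^-1 {G_inv.shape} and A22^-1 {A22_inv.shape} differ in size")
    if len(genotyped_index) != G_inv.shape[0]:
        raise ValueError("genotyped index length does not match G^-1")
    H_inv = A_inv.copy()
    ix = np.ix_(genotyped_index, genotyped_index)
    H_inv[ix] += G_inv - A22_inv
    return H_inv


def design_matrices(
    phenotypes: pd.DataFrame, animal_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Incidence matrices X (records x CG) and W (records x animals).

    Contemporary groups are coded without an intercept (one column per
    level), the full-rank coding for a single fixed effect.
    """
    index = {a: i for i, a in enumerate(animal_ids)}
    unknown = [a for a in phenotypes["animal"].astype(str) if a not in index]
    if unknown:
        raise ValueError(f"phenotyped animals absent from pedigree: {unknown[:10]}")
    cg_levels = sorted(phenotypes["cg"].astype(str).unique())
    cg_pos = {c: j for j, c in enumerate(cg_levels)}
    nrec = len(phenotypes)
    X = np.zeros((nrec, len(cg_levels)))
    W = np.zeros((nrec, len(animal_ids)))
    for r, (a, c) in enumerate(zip(phenotypes["animal"].astype(str), phenotypes["cg"].astype(str))):
        X[r, cg_pos[c]] = 1.0
        W[r, index[a]] = 1.0
    y = phenotypes["value"].to_numpy(dtype=float)
    return y, X, W, cg_levels


def assemble_mme(
    y: np.ndarray, X: np.ndarray, W: np.ndarray, H_inv: np.ndarray, vc: VarianceComponents
) -> tuple[np.ndarray, np.ndarray]:
    """Lambda-form MME: LHS = [[X'X, X'W], [W'X, W'W + H^-1 lambda]]."""
    XtX = X.T @ X
    XtW = X.T @ W
    WtW = W.T @ W
    LHS = np.block([[XtX, XtW], [XtW.T, WtW + H_inv * vc.lam]])
    RHS = np.concatenate([X.T @ y, W.T @ y])
    return LHS, RHS


def solve_mme(LHS: np.ndarray, RHS: np.ndarray, n_fixed: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve the MME by symmetric factorization; returns (beta_hat, u_hat)."""
    try:
        c = cho_factor(LHS)
    except np.linalg.LinAlgError as err:
        diag = np.diag(LHS)
        worst = int(np.argmin(diag))
        kind = "fixed effect" if worst < n_fixed else "animal"
        raise ValueError(f"singular MME coefficient matrix (suspect {kind} {worst})") from err
    sol = cho_solve(c, RHS)
    return sol[:n_fixed], sol[n_fixed:]


def invert_lhs(LHS: np.ndarray, sigma2_e: float) -> np.ndarray:
    """Full inverse of the lambda-form LHS, rescaled by sigma_e^2.

    The rescaling puts the returned matrix on the variance scale of the
    unscaled equations, so its animal diagonal is PEV directly.
    """
    try:
        c = cho_factor(LHS)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular MME coefficient matrix") from err
    C = cho_solve(c, np.eye(LHS.shape[0])) * sigma2_e
    return 0.5 * (C + C.T)


def acc_gebv(pev: np.ndarray, sigma2_u: float) -> tuple[np.ndarray, int]:
    """Accuracy sqrt(1 - PEV/sigma_u^2), floored at 0.

    Returns the accuracy vector and the number of animals floored (PEV
    exceeding sigma_u^2, possible for inbred or data-poor animals).
    """
    pev = np.asarray(pev, float)
    if np.any(pev < -1e-8):
        raise ValueError("negative PEV: upstream numerical failure")
    rel = 1.0 - pev / sigma2_u
    floored = int(np.sum(rel < 0))
    return np.sqrt(np.clip(rel, 0.0, None)), floored


class SingleStepGBLUP(BaseEstimator):
    """Single-step GBLUP animal model with a contemporary-group fixed effect.

    Combines the pedigree relationship matrix A with a blended/tuned
    genomic relationship matrix G (direct or APY inverse) into H^-1 and
    solves the dense mixed-model equations.

    Parameters
    ----------
    sigma2_u, sigma2_e : additive and residual variance (treated as known).
    alpha : blending proportion of A22 in G.
    tune : apply mean-compatibility tuning (delta, b).
    tune_on : "pre_blend" (default) tunes the mixture entering H^-1, "g0"
        tunes raw G0.
    inverse : "direct" or "apy".
    core_size : APY core size; None means the eigenvalue rule at
        ``core_threshold``.
    core_threshold : fraction of variance in G the core eigenvalues explain.
    seed : seed for random core selection.

    Attributes (after :meth:`fit`)
    ------------------------------
    beta_hat_, u_hat_ : fixed-effect and GEBV solutions.
    pev_, acc_ : per-animal prediction error variance and accuracy.
    C_uu_ : animal block of the rescaled MME inverse (PEC of GEBV).
    C_u2u2_ : its genotyped sub-block.
    grm_ : the :class:`GrmBundle` used (None for pedigree-only fits).
    """

    def __init__(
        self,
        sigma2_u: float = 1.0,
        sigma2_e: float = 1.0,
        alpha: float = 0.05,
        tune: bool = True,
        tune_on: str = "pre_blend",
        inverse: str = "direct",
        core_size: int | None = None,
        core_threshold: float = 0.99,
        seed: int = 0,
    ) -> None:
        self.sigma2_u = sigma2_u
        self.sigma2_e = sigma2_e
        self.alpha = alpha
        self.tune = tune
        self.tune_on = tune_on
        self.inverse = inverse
        self.core_size = core_size
        self.core_threshold = core_threshold
        self.seed = seed

    def fit(
        self,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix | None,
        phenotypes: pd.DataFrame,
        freqs: AlleleFrequencySet | None = None,
    ) -> "SingleStepGBLUP":
        vc = VarianceComponents(self.sigma2_u, self.sigma2_e)
        self.vc_ = vc
        self.pedigree_ = pedigree
        self.animal_ids_ = pedigree.ids

        if genotypes is not None and genotypes.n_animals > 0:
            rel = relationship_matrices(pedigree, list(genotypes.ids))
            core_ids = None
            if self.inverse == "apy" and self.core_size is not None:
                from .genomic import select_core

                core_ids = select_core(list(genotypes.ids), self.core_size, self.seed)
            grm = build_grm(
                genotypes,
                rel.A22,
                alpha=self.alpha,
                tune=self.tune,
                tune_on=self.tune_on,
                freqs=freqs,
                inverse=self.inverse,
                core_ids=core_ids,
                core_threshold=self.core_threshold,
                core_seed=self.seed,
            )
            gidx = pedigree.index_of(list(genotypes.ids))
            H_inv = build_H_inverse(rel.A_inv, rel.A22_inv, grm.G_inv, gidx)
            self.grm_: GrmBundle | None = grm
            self._genotypes_ = genotypes
            self.genotyped_ids_ = list(genotypes.ids)
            self.genotyped_index_ = gidx
        else:
            from .pedigree import build_A_inverse, compute_inbreeding

            F = compute_inbreeding(pedigree)
            H_inv = build_A_inverse(pedigree, F)
            self.grm_ = None
            self._genotypes_ = None
            self.genotyped_ids_ = []
            self.genotyped_index_ = np.empty(0, dtype=np.intp)
        self.H_inv_ = H_inv

        y, X, W, cg_levels = design_matrices(phenotypes, self.animal_ids_)
        LHS, RHS = assemble_mme(y, X, W, H_inv, vc)
        self.cg_levels_ = cg_levels
        self.n_fixed_ = len(cg_levels)
        self.beta_hat_, self.u_hat_ = solve_mme(LHS, RHS, self.n_fixed_)

        C = invert_lhs(LHS, vc.sigma2_e)
        nf = self.n_fixed_
        self.C_uu_ = C[nf:, nf:]
        self.pev_ = np.diag(self.C_uu_).copy()
        if len(self.genotyped_ids_):
            ix = np.ix_(self.genotyped_index_, self.genotyped_index_)
            self.C_u2u2_ = self.C_uu_[ix]
        else:
            self.C_u2u2_ = np.empty((0, 0))
        self.acc_, self.n_floored_ = acc_gebv(self.pev_, vc.sigma2_u)
        return self

    # -- convenience accessors -------------------------------------------

    def gebv(self, ids: list[str]) -> np.ndarray:
        """GEBV for the given animals (must be in the pedigree)."""
        return self.u_hat_[self.pedigree_.index_of(ids)]

    def accuracy(self, ids: list[str]) -> np.ndarray:
        return self.acc_[self.pedigree_.index_of(ids)]

    def u2_hat(self) -> np.ndarray:
        """GEBV restricted to genotyped animals, in genotype-row order."""
        return self.u_hat_[self.genotyped_index_]
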