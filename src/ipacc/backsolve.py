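"""Backsolving SNP effects and their prediction-error covariances (PEC)
from a single-step GBLUP evaluation, and indirect predictions (IP) with
per-animal theoretical accuracies.

The chain is: GEBV of genotyped animals -> SNP effects
a_hat = (1-alpha) b (1/k) Z' G^-1 u2_hat, then the estimator variance
var(a_hat) propagated from the GEBV PEC block of the MME inverse, and
finally the SNP prediction-error covariance

    pec = sigma_a^2 I - var(a_hat),    sigma_a^2 = (1-alpha) b sigma_u^2 / k.

``var(a_hat)`` shrinks to 0 with no data and grows as records accumulate,
so the complement against the per-SNP prior variance sigma_a^2 is the
quantity that plays the prediction-error role in the accuracy
acc_ip = sqrt(1 - z pec z' / sigma_u^2); in the unblended fully genotyped
limit it equals the C^gg block of the SNP-BLUP equations exactly, and
acc_ip coincides with the GEBV accuracy of training animals.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .genomic import AlleleFrequencySet, CenteredGenotypes, GenotypeMatrix, center_genotypes
from .mme import SingleStepGBLUP

__all__ = [
    "SnpEffectPosterior",
    "backsolve_snp_effects",
    "compute_var_ahat",
    "compute_snp_pec",
    "indirect_predict",
    "acc_ip",
    "write_pec",
    "read_pec",
    "freq_checksum",
    "IndirectPredictor",
]

_PEC_MAGIC = b"IPACCPEC"


@dataclass
class SnpEffectPosterior:
    """Backsolved SNP effects with their variance/PEC and provenance."""

    a_hat: np.ndarray | None
    sigma2_a: float
    var_ahat: np.ndarray | None
    pec: np.ndarray | None
    alpha: float
    b: float
    k: float
    sigma2_u: float
    freq_crc: int


def backsolve_snp_effects(
    Z: CenteredGenotypes | np.ndarray,
    G_inv: np.ndarray,
    u2_hat: np.ndarray,
    alpha: float,
    b: float,
    k: float,
) -> np.ndarray:
    """a_hat = (1-alpha) b (1/k) Z' G^-1 u2_hat.

    ``u2_hat`` must be the GEBV of the genotyped animals in the row order
    of Z, and ``G_inv`` the inverse of the same blended/tuned G used in
    the evaluation.
    """
    Zm = Z.Z if isinstance(Z, CenteredGenotypes) else np.asarray(Z, float)
    if Zm.shape[0] != u2_hat.shape[0]:
        raise ValueError(
            f"Z has {Zm.shape[0]} genotyped rows but u2_hat has {u2_hat.shape[0]} entries"
        )
    return (1.0 - alpha) * b / k * (Zm.T @ (G_inv @ u2_hat))


def compute_var_ahat(
    Z: CenteredGenotypes | np.ndarray,
    G_inv: np.ndarray,
    C_u2u2: np.ndarray,
    sigma2_u: float,
    alpha: float,
    b: float,
    k: float,
) -> np.ndarray:
    """Estimator variance of the backsolved SNP effects.

    var(a_hat) = c^2 (Z'G^-1 Z sigma_u^2 - Z'G^-1 C_u2u2 G^-1 Z) with
    c = (1-alpha) b / k; symmetrized to absorb round-off. C_u2u2 is the
    genotyped block of the (rescaled) MME inverse of the same evaluation.

    Only G^-1 enters, never G itself: when G^-1 is an APY inverse this
    keeps the expression consistent with the relationship matrix the MME
    actually used (the implied APY G), which guarantees the result stays
    positive semi-definite.
    """
    Zm = Z.Z if isinstance(Z, CenteredGenotypes) else np.asarray(Z, float)
    if C_u2u2.shape[0] != Zm.shape[0]:
        raise ValueError("C_u2u2 dimension does not match the number of genotyped animals")
    c = (1.0 - alpha) * b / k
    T = G_inv @ Zm  # n_g x m
    V = c * c * (Zm.T @ T * sigma2_u - T.T @ C_u2u2 @ T)
    return 0.5 * (V + V.T)


def compute_snp_pec(var_ahat: np.ndarray, sigma2_a: float) -> np.ndarray:
    """pec = sigma_a^2 I - var(a_hat); errors if materially indefinite."""
    if sigma2_a <= 0:
        raise ValueError("per-SNP prior variance sigma2_a must be positive")
    pec = sigma2_a * np.eye(var_ahat.shape[0]) - var_ahat
    lo = float(np.linalg.eigvalsh(pec)[0])
    if lo < -1e-6 * sigma2_a:
        raise ValueError(f"SNP PEC is indefinite (min eigenvalue {lo:.3e}); inconsistent inputs")
    return pec


def indirect_predict(Z_target: CenteredGenotypes | np.ndarray, a_hat: np.ndarray) -> np.ndarray:
    """IP_j = z_j . a_hat for each target animal."""
    Zm = Z_target.Z if isinstance(Z_target, CenteredGenotypes) else np.asarray(Z_target, float)
    if Zm.shape[1] != a_hat.shape[0]:
        raise ValueError(f"target has {Zm.shape[1]} SNPs, effects have {a_hat.shape[0]}")
    return Zm @ a_hat


def acc_ip(
    Z_target: CenteredGenotypes | np.ndarray,
    pec: np.ndarray,
    sigma2_u: float,
    polygenic_share: float = 0.0,
) -> tuple[np.ndarray, int]:
    """Per-animal IP accuracy, floored at 0.

    acc_j = sqrt(1 - (z_j pec z_j' + polygenic_share * sigma_u^2) / sigma_u^2)

    ``polygenic_share`` is the fraction of the additive variance the
    markers do not carry under blending: the blended model decomposes a
    genotyped animal's breeding value into a marker part (prior variance
    (1-alpha) b g0_jj sigma_u^2, whose estimation error is z pec z') and a
    polygenic remainder the indirect prediction cannot touch. For an
    average non-inbred animal that remainder is (1 - (1-alpha) b) of
    sigma_u^2 — the complement of the marker-share coefficient; the
    mean-inflation of the tuned G (the delta term) affects benchmark and
    indirect accuracies alike through b and cancels in their comparison.
    With alpha = 0 and no tuning the share is 0 and the accuracy reduces
    to the exact SNP-BLUP expression.

    Returns the accuracy vector and the count of floored animals.
    """
    Zm = Z_target.Z if isinstance(Z_target, CenteredGenotypes) else np.asarray(Z_target, float)
    if Zm.ndim == 1:
        Zm = Zm[None, :]
    pev_ip = np.einsum("ij,jk,ik->i", Zm, pec, Zm)
    if np.any(pev_ip < -1e-8 * sigma2_u):
        raise ValueError("negative IP prediction error variance: PEC is inconsistent")
    pev_ip = np.clip(pev_ip, 0.0, None) + polygenic_share * sigma2_u
    rel = 1.0 - pev_ip / sigma2_u
    floored = int(np.sum(rel < 0))
    return np.sqrt(np.clip(rel, 0.0, None)), floored


def freq_checksum(p: np.ndarray) -> int:
    """CRC32 of the allele-frequency vector (rounded to 1e-9)."""
    return zlib.crc32(np.round(np.asarray(p, float), 9).tobytes())


def write_pec(post: SnpEffectPosterior, path: str | Path) -> None:
    """Binary PEC file: magic, header (m, alpha, b, k, sigma2_u, freq CRC),
    then the m x m doubles row-major. Lossless for float64."""
    pec = np.ascontiguousarray(post.pec, dtype=np.float64)
    m = pec.shape[0]
    with open(path, "wb") as fh:
        fh.write(_PEC_MAGIC)
        fh.write(struct.pack("<qddddI", m, post.alpha, post.b, post.k, post.sigma2_u, post.freq_crc))
        fh.write(pec.tobytes())


def read_pec(path: str | Path, freqs: AlleleFrequencySet | None = None) -> SnpEffectPosterior:
    """Read a PEC file; refuses truncated files and, when ``freqs`` is
    supplied, files whose frequency checksum does not match."""
    raw = Path(path).read_bytes()
    if raw[: len(_PEC_MAGIC)] != _PEC_MAGIC:
        raise ValueError(f"{path}: not a PEC file (bad magic bytes)")
    header = struct.Struct("<qddddI")
    off = len(_PEC_MAGIC)
    if len(raw) < off + header.size:
        raise ValueError(f"{path}: truncated PEC header")
    m, alpha, b, k, sigma2_u, crc = header.unpack_from(raw, off)
    body = raw[off + header.size :]
    if len(body) != 8 * m * m:
        raise ValueError(f"{path}: truncated PEC body ({len(body)} bytes, expected {8 * m * m})")
    if freqs is not None and freq_checksum(freqs.p) != crc:
        raise ValueError(f"{path}: allele-frequency checksum mismatch")
    pec = np.frombuffer(body, dtype=np.float64).reshape(m, m).copy()
    sigma2_a = (1.0 - alpha) * b * sigma2_u / k
    return SnpEffectPosterior(None, sigma2_a, None, pec, alpha, b, k, sigma2_u, crc)


def write_snp_effects(a_hat: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(a_hat):
            fh.write(f"{i} {float(a)!r}\n")


def read_snp_effects(path: str | Path) -> np.ndarray:
    vals = [float(line.split()[1]) for line in open(path) if line.strip()]
    return np.asarray(vals)


class IndirectPredictor(BaseEstimator):
    """Marker-based predictor for animals outside an ssGBLUP evaluation.

    ``fit`` backsolves SNP effects from one fitted :class:`SingleStepGBLUP`
    (the official, "direct" evaluation) and builds the SNP PEC from a
    second fitted model (by default the same one) whose MME inverse
    supplies the GEBV PEC block — this mirrors interim evaluations where
    the SNP effects come from the full run but the PEC may be computed on
    a genotype subset. ``predict`` returns IP; ``accuracy`` returns the
    theoretical per-animal accuracy.

    Target genotypes are centered with the training run's allele
    frequencies.
    """

    def __init__(self, compute_pec: bool = True) -> None:
        self.compute_pec = compute_pec

    def fit(
        self,
        model: SingleStepGBLUP,
        pec_model: SingleStepGBLUP | None = None,
    ) -> "IndirectPredictor":
        if model.grm_ is None:
            raise ValueError("the training evaluation has no genomic component")
        grm = model.grm_
        self.freqs_ = grm.freqs
        self.sigma2_u_ = model.vc_.sigma2_u
        # centered genotypes of the training run's genotyped animals
        Z = self._center_training(model)
        self.a_hat_ = backsolve_snp_effects(Z, grm.G_inv, model.u2_hat(), grm.alpha, grm.b, grm.freqs.k)
        self.alpha_, self.b_, self.k_ = grm.alpha, grm.b, grm.freqs.k

        if self.compute_pec:
            src = model if pec_model is None else pec_model
            if src.grm_ is None:
                raise ValueError("the PEC evaluation has no genomic component")
            sg = src.grm_
            Zs = self._center_training(src)
            sigma2_a = (1.0 - sg.alpha) * sg.b * src.vc_.sigma2_u / sg.freqs.k
            self.var_ahat_ = compute_var_ahat(
                Zs, sg.G_inv, src.C_u2u2_, src.vc_.sigma2_u, sg.alpha, sg.b, sg.freqs.k
            )
            self.sigma2_a_ = sigma2_a
            self.pec_ = compute_snp_pec(self.var_ahat_, sigma2_a)
            self.polygenic_share_ = 1.0 - (1.0 - sg.alpha) * sg.b
        else:
            self.var_ahat_ = None
            self.sigma2_a_ = (1.0 - grm.alpha) * grm.b * model.vc_.sigma2_u / grm.freqs.k
            self.pec_ = None
            self.polygenic_share_ = 1.0 - (1.0 - grm.alpha) * grm.b
        return self

    @staticmethod
    def _center_training(model: SingleStepGBLUP) -> CenteredGenotypes:
        gm = model._genotypes_
        return center_genotypes(gm, model.grm_.freqs)

    def posterior(self) -> SnpEffectPosterior:
        return SnpEffectPosterior(
            self.a_hat_,
            self.sigma2_a_,
            self.var_ahat_,
            self.pec_,
            self.alpha_,
            self.b_,
            self.k_,
            self.sigma2_u_,
            freq_checksum(self.freqs_.p),
        )

    def _center(self, genotypes: GenotypeMatrix | CenteredGenotypes | np.ndarray):
        if isinstance(genotypes, GenotypeMatrix):
            return center_genotypes(genotypes, self.freqs_)
        return genotypes

    def predict(self, genotypes: GenotypeMatrix | CenteredGenotypes | np.ndarray) -> np.ndarray:
        """Indirect predictions z_j . a_hat for the given animals."""
        return indirect_predict(self._center(genotypes), self.a_hat_)

    def accuracy(self, genotypes: GenotypeMatrix | CenteredGenotypes | np.ndarray) -> np.ndarray:
        """Theoretical accuracy of IP for the given animals."""
        if self.pec_ is None:
            raise ValueError("fit with compute_pec=True to obtain accuracies")
        acc, self.n_floored_ = acc_ip(
            self._center(genotypes), self.pec_, self.sigma2_u_, self.polygenic_share_
        )
        return acc
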