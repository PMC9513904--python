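"""Genomic relationship matrices: VanRaden G0, blending/tuning, direct and
APY inversion, and eigenvalue-based core-size selection.

Genotypes are allele dosages in {0, 1, 2}; missing cells (a configurable
single-digit code) are imputed at the population mean when centering, which
keeps the centered value 0 and leaves G0 well defined. Monomorphic SNPs are
retained as zero centered columns so SNP indexing is stable across subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencySet",
    "CenteredGenotypes",
    "GrmBundle",
    "ApyStructure",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
    "center_genotypes",
    "build_G0",
    "compute_tuning",
    "blend_tune",
    "invert_grm",
    "core_count_from_variance",
    "apy_inverse",
    "select_core",
    "build_grm",
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (animals x SNPs) with a missing-value mask."""

    M: np.ndarray  # int dosages, missing cells hold the missing code
    ids: list[str]
    missing_code: int = 5

    @property
    def n_animals(self) -> int:
        return self.M.shape[0]

    @property
    def n_snps(self) -> int:
        return self.M.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.M == self.missing_code

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise KeyError(f"animals without genotypes: {missing[:10]}")
        rows = [index[a] for a in ids]
        return GenotypeMatrix(self.M[rows], list(ids), self.missing_code)


@dataclass
class AlleleFrequencySet:
    """Reference-allele frequencies and the VanRaden scaling constant."""

    p: np.ndarray
    k: float  # 2 * sum p_i (1 - p_i)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("no polymorphic SNPs: scaling constant k must be > 0")


@dataclass
class CenteredGenotypes:
    """Dosages centered by twice the allele frequency (z_ij = m_ij - 2 p_j)."""

    Z: np.ndarray
    ids: list[str]

    def row(self, animal_id: str) -> np.ndarray:
        return self.Z[self.ids.index(animal_id)]


@dataclass
class GrmBundle:
    """Blended/tuned genomic relationship matrix and its inverse."""

    G0: np.ndarray
    G: np.ndarray
    G_inv: np.ndarray
    alpha: float
    delta: float
    b: float
    freqs: AlleleFrequencySet
    ids: list[str]
    apy: "ApyStructure | None" = None

    @property
    def n_g(self) -> int:
        return self.G.shape[0]


@dataclass
class ApyStructure:
    """Core/non-core decomposition behind the APY inverse of G."""

    core_ids: list[str]
    m_nn: np.ndarray
    G_apy_inv: np.ndarray


def read_genotypes(path: str | Path, missing_code: int = 5) -> GenotypeMatrix:
    """Read a BLUPF90-style genotype file: ``animal_id <digit string>``."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    width = None
    allowed = {0, 1, 2, missing_code}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'id digits', got {len(parts)} fields")
            animal, digits = parts
            row = np.frombuffer(digits.encode(), dtype=np.uint8) - ord("0")
            if width is None:
                width = row.size
            elif row.size != width:
                raise ValueError(f"line {lineno}: ragged row ({row.size} SNPs, expected {width})")
            bad = set(np.unique(row)) - allowed
            if bad:
                raise ValueError(f"line {lineno}: invalid dosage digits {sorted(bad)}")
            ids.append(animal)
            rows.append(row.astype(np.int8))
    if not rows:
        raise ValueError(f"empty genotype file: {path}")
    return GenotypeMatrix(np.vstack(rows), ids, missing_code)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for animal, row in zip(gm.ids, gm.M):
            fh.write(f"{animal} {''.join(map(str, row))}\n")


def allele_frequencies(gm: GenotypeMatrix, subset: list[str] | None = None) -> AlleleFrequencySet:
    """Per-SNP reference-allele frequency p_j = mean(dosage_j)/2 over the
    (sub)population, skipping missing cells, with k = 2 sum p_j (1-p_j)."""
    sub = gm if subset is None else gm.subset(subset)
    M = sub.M.astype(float)
    mask = sub.missing_mask
    M[mask] = np.nan
    counts = (~mask).sum(axis=0)
    if np.any(counts == 0):
        snp = int(np.argmax(counts == 0))
        raise ValueError(f"SNP {snp} has no observed genotypes in the subset")
    p = np.nanmean(M, axis=0) / 2.0
    k = float(2.0 * np.sum(p * (1.0 - p)))
    return AlleleFrequencySet(p, k)


def center_genotypes(gm: GenotypeMatrix, freqs: AlleleFrequencySet) -> CenteredGenotypes:
    """z_ij = m_ij - 2 p_j; missing cells become 0 (mean imputation)."""
    if freqs.p.size != gm.n_snps:
        raise ValueError(f"frequency length {freqs.p.size} != SNP count {gm.n_snps}")
    Z = gm.M.astype(float) - 2.0 * freqs.p
    Z[gm.missing_mask] = 0.0
    return CenteredGenotypes(Z, list(gm.ids))


def build_G0(Z: CenteredGenotypes | np.ndarray, k: float) -> np.ndarray:
    """VanRaden type-1 genomic relationship matrix G0 = Z Z' / k."""
    if k <= 0:
        raise ValueError("scaling constant k must be positive")
    Zm = Z.Z if isinstance(Z, CenteredGenotypes) else np.asarray(Z, float)
    G0 = Zm @ Zm.T / k
    return 0.5 * (G0 + G0.T)


def compute_tuning(G_pre: np.ndarray, A22: np.ndarray) -> tuple[float, float]:
    """Mean-compatibility tuning: delta = mean(A22) - mean(G), b = 1 - delta/2."""
    n = G_pre.shape[0]
    delta = float((A22.sum() - G_pre.sum()) / n**2)
    return delta, 1.0 - 0.5 * delta


def blend_tune(
    G0: np.ndarray,
    A22: np.ndarray,
    alpha: float,
    delta: float,
    b: float,
) -> np.ndarray:
    """G = b((1-alpha) G0 + alpha A22) + delta added to every entry."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("blending parameter alpha must be in [0, 1)")
    G = b * ((1.0 - alpha) * G0 + alpha * A22) + delta
    return 0.5 * (G + G.T)


def invert_grm(G: np.ndarray) -> np.ndarray:
    """Symmetric (Cholesky) inverse of a positive-definite G."""
    try:
        c = cho_factor(G)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "G is not positive definite; increase the blending proportion alpha"
        ) from err
    G_inv = cho_solve(c, np.eye(G.shape[0]))
    return 0.5 * (G_inv + G_inv.T)


def core_count_from_variance(G: np.ndarray, threshold: float) -> int:
    """Smallest number of leading eigenvalues of G explaining ``threshold``
    of its total variance (the APY core-size rule)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    vals = np.linalg.eigvalsh(G)[::-1]
    vals = np.clip(vals, 0.0, None)
    frac = np.cumsum(vals) / vals.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def select_core(ids: list[str], n_core: int, seed: int) -> list[str]:
    """Uniform random core subset without replacement, reproducible by seed."""
    if n_core > len(ids):
        raise ValueError(f"n_core={n_core} exceeds number of genotyped animals {len(ids)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_core, replace=False)
    return [ids[i] for i in sorted(chosen)]


def apy_inverse(G: np.ndarray, ids: list[str], core_ids: list[str]) -> ApyStructure:
    """APY inverse of G from a core/non-core partition.

    Non-core animals get a diagonal Mendelian-error term
    m_nn,i = g_ii - G_ic Gcc^-1 G_ci; the assembled inverse preserves the
    caller's animal ordering.
    """
    index = {a: i for i, a in enumerate(ids)}
    core_idx = np.asarray([index[a] for a in core_ids], dtype=np.intp)
    noncore_idx = np.asarray([i for i in range(len(ids)) if ids[i] not in set(core_ids)], dtype=np.intp)

    Gcc = G[np.ix_(core_idx, core_idx)]
    try:
        c = cho_factor(Gcc)
    except np.linalg.LinAlgError as err:
        raise ValueError("core block Gcc is not positive definite") from err
    Gcc_inv = cho_solve(c, np.eye(Gcc.shape[0]))

    n = G.shape[0]
    G_apy = np.zeros((n, n))
    if noncore_idx.size == 0:
        G_apy[np.ix_(core_idx, core_idx)] = Gcc_inv
        return ApyStructure(list(core_ids), np.empty(0), 0.5 * (G_apy + G_apy.T))

    Gcn = G[np.ix_(core_idx, noncore_idx)]
    S = cho_solve(c, Gcn)  # Gcc^-1 Gcn
    m_nn = np.diag(G)[noncore_idx] - np.einsum("ij,ij->j", Gcn, S)
    bad = np.where(m_nn <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive Mendelian error term for animal {ids[noncore_idx[bad[0]]]!r}; "
            "the core is numerically singular"
        )
    Minv = 1.0 / m_nn

    G_apy[np.ix_(core_idx, core_idx)] = Gcc_inv + (S * Minv) @ S.T
    G_apy[np.ix_(core_idx, noncore_idx)] = -S * Minv
    G_apy[np.ix_(noncore_idx, core_idx)] = (-S * Minv).T
    G_apy[noncore_idx, noncore_idx] = Minv
    return ApyStructure(list(core_ids), m_nn, 0.5 * (G_apy + G_apy.T))


def build_grm(
    gm: GenotypeMatrix,
    A22: np.ndarray,
    *,
    alpha: float = 0.05,
    tune: bool = True,
    tune_on: str = "pre_blend",
    freqs: AlleleFrequencySet | None = None,
    inverse: str = "direct",
    core_ids: list[str] | None = None,
    core_threshold: float = 0.99,
    core_seed: int = 0,
) -> GrmBundle:
    """Build the blended/tuned G and its inverse for one evaluation.

    ``tune_on`` selects whether the mean-compatibility tuning is computed
    from the pre-blend mixture (1-alpha) G0 + alpha A22 (default) or from
    raw G0 (``"g0"``). With ``inverse="apy"`` the inverse is assembled from
    a random core of size ``core_count_from_variance(G, core_threshold)``
    unless ``core_ids`` is given.
    """
    if freqs is None:
        freqs = allele_frequencies(gm)
    Z = center_genotypes(gm, freqs)
    G0 = build_G0(Z, freqs.k)
    if tune:
        base = (1.0 - alpha) * G0 + alpha * A22 if tune_on == "pre_blend" else G0
        delta, b = compute_tuning(base, A22)
    else:
        delta, b = 0.0, 1.0
    G = blend_tune(G0, A22, alpha, delta, b)

    apy = None
    if inverse == "apy":
        if core_ids is None:
            n_core = core_count_from_variance(G, core_threshold)
            core_ids = select_core(list(gm.ids), n_core, core_seed)
        apy = apy_inverse(G, list(gm.ids), core_ids)
        G_inv = apy.G_apy_inv
    elif inverse == "direct":
        G_inv = invert_grm(G)
    else:
        raise ValueError(f"unknown inverse mode {inverse!r}")
    return GrmBundle(G0, G, G_inv, alpha, delta, b, freqs, list(gm.ids), apy)
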