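"""Synthetic breeding-population generator.

Produces the data structure the single-step machinery assumes: a
multi-generation pedigree with variable (sire-skewed) family sizes,
unlinked biallelic SNPs transmitted by gene dropping, marker-driven
breeding values, phenotypes with a contemporary-group fixed effect, and a
final-generation cohort of genotyped animals with no phenotypes and no
progeny that plays the role of the young validation animals.

Family-size variation is deliberate: a handful of heavily used sires
produce large half-sib families, which is what creates the wide spread of
theoretical accuracies the calibration metrics need. Loci are unlinked and
the true breeding value is entirely marker-driven, so the unblended
model-equivalence identities hold exactly on simulated data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix, write_genotypes
from .pedigree import Pedigree

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedData",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_phenotypes",
    "make_validation_split",
    "simulate",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic population.

    Defaults give the standard benchmark: ~2,500 animals in 5 discrete
    generations, 1,000 unlinked SNPs, h^2 = 0.4, roughly 1,700 genotyped
    training animals and ~250 genotyped validation animals in the final
    generation.
    """

    seed: int
    n_founders: int = 150
    generation_sizes: tuple[int, ...] = (600, 600, 600, 550)
    n_sires: int = 25
    sire_concentration: float = 0.35  # Dirichlet mass; small = skewed usage
    m: int = 1000
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    h2: float = 0.4
    sigma2_u: float = 0.4
    cg_sd: float = 0.5
    n_cg_per_generation: int = 6
    genotyping_prob: tuple[float, ...] = (0.5, 0.85, 0.95, 0.95, 0.45)

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        lo, hi = self.founder_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("founder frequencies must lie strictly inside (0, 1)")
        if len(self.genotyping_prob) != len(self.generation_sizes) + 1:
            raise ValueError("need one genotyping probability per generation (founders included)")

    @property
    def sigma2_e(self) -> float:
        return self.sigma2_u * (1.0 - self.h2) / self.h2


@dataclass
class SimulatedTruth:
    """True SNP effects, breeding values and phenotype components."""

    a_true: np.ndarray
    u_true: np.ndarray  # per animal, pedigree order
    founder_freqs: np.ndarray
    cg_effects: dict[str, float]
    y: pd.DataFrame


@dataclass
class SimulatedData:
    """One simulated dataset plus its validation split.

    ``pedigree``/``genotypes``/``phenotypes`` are the *full* data (the
    benchmark evaluation); the ``training_*`` accessors drop the
    validation animals' pedigree records and genotypes entirely,
    mimicking young animals absent from the official evaluation.
    """

    config: SimulationConfig
    pedigree: Pedigree
    generation: np.ndarray
    genotypes: GenotypeMatrix  # all genotyped animals incl. validation
    phenotypes: pd.DataFrame
    truth: SimulatedTruth
    validation_ids: list[str]
    training_genotyped_ids: list[str]

    def training_pedigree(self) -> Pedigree:
        drop = set(self.validation_ids)
        recs = [r for r in self.pedigree.records if r[0] not in drop]
        return Pedigree(recs)

    def training_genotypes(self) -> GenotypeMatrix:
        return self.genotypes.subset(self.training_genotyped_ids)

    def validation_genotypes(self) -> GenotypeMatrix:
        return self.genotypes.subset(self.validation_ids)


def simulate_pedigree(cfg: SimulationConfig) -> tuple[Pedigree, np.ndarray, np.ndarray]:
    """Discrete-generation pedigree with skewed sire usage.

    Returns (pedigree, generation, sex) with sex coded 0 = male,
    1 = female. Parents always come from the previous generation and the
    two parents of an animal are always distinct (separate sexes).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    records: list[tuple[str, str, str]] = []
    generation: list[int] = []
    sex: list[int] = []
    next_id = 1

    cohorts: list[list[int]] = []
    cohort = []
    for _ in range(cfg.n_founders):
        records.append((str(next_id), "0", "0"))
        generation.append(0)
        sex.append(int(rng.integers(2)))
        cohort.append(next_id)
        next_id += 1
    cohorts.append(cohort)

    for g, size in enumerate(cfg.generation_sizes, start=1):
        prev = cohorts[-1]
        males = [a for a in prev if sex[a - 1] == 0]
        females = [a for a in prev if sex[a - 1] == 1]
        if not males or not females:
            raise RuntimeError("a generation lacks one sex; enlarge the population")
        n_sires = min(cfg.n_sires, len(males))
        sires = rng.choice(males, size=n_sires, replace=False)
        weights = rng.dirichlet(np.full(n_sires, cfg.sire_concentration))
        cohort = []
        for _ in range(size):
            s = int(rng.choice(sires, p=weights))
            d = int(rng.choice(females))
            records.append((str(next_id), str(s), str(d)))
            generation.append(g)
            sex.append(int(rng.integers(2)))
            cohort.append(next_id)
            next_id += 1
        cohorts.append(cohort)
    return Pedigree(records), np.asarray(generation), np.asarray(sex)


def drop_genotypes(
    ped: Pedigree, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Gene dropping over the whole pedigree.

    Founders receive two alleles per locus sampled Bernoulli(p_j) with
    p_j uniform over the configured range; descendants inherit one
    uniformly chosen allele from each parent per locus, loci independent.
    Returns (dosages for every animal, founder frequencies p).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    n, m = len(ped), cfg.m
    p = rng.uniform(*cfg.founder_freq_range, size=m)
    H = np.zeros((n, 2, m), dtype=np.uint8)
    par = ped.parent_indices()
    for i in range(n):
        s, d = par[i]
        for slot, parent in enumerate((s, d)):
            if parent < 0:
                H[i, slot] = rng.random(m) < p
            else:
                pick = rng.integers(2, size=m)
                H[i, slot] = H[parent, pick, np.arange(m)]
    return H.sum(axis=1).astype(np.int8), p


def simulate_phenotypes(
    ped: Pedigree,
    dosages: np.ndarray,
    founder_freqs: np.ndarray,
    generation: np.ndarray,
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, SimulatedTruth]:
    """Marker-driven breeding values and CG-structured phenotypes.

    a_true ~ N(0, sigma_u^2 / k) with k = 2 sum p(1-p) over founder
    frequencies, u_true = Z a_true; phenotypes y = CG + u + e for every
    animal of the intermediate generations (founders and the final
    generation carry no records).
    """
    rng = np.random.default_rng([cfg.seed, 3])
    k_true = 2.0 * np.sum(founder_freqs * (1.0 - founder_freqs))
    a_true = rng.normal(0.0, np.sqrt(cfg.sigma2_u / k_true), size=cfg.m)
    Z_true = dosages.astype(float) - 2.0 * founder_freqs
    u_true = Z_true @ a_true

    last_gen = generation.max()
    phenotyped = (generation > 0) & (generation < last_gen)
    ids = np.asarray(ped.ids)

    rows = []
    cg_effects: dict[str, float] = {}
    for g in range(1, last_gen):
        members = np.where(phenotyped & (generation == g))[0]
        labels = rng.integers(cfg.n_cg_per_generation, size=members.size)
        for c in range(cfg.n_cg_per_generation):
            cg_effects[f"g{g}c{c}"] = float(rng.normal(0.0, cfg.cg_sd))
        e = rng.normal(0.0, np.sqrt(cfg.sigma2_e), size=members.size)
        for j, idx in enumerate(members):
            cg = f"g{g}c{labels[j]}"
            rows.append((ids[idx], cg, cg_effects[cg] + u_true[idx] + e[j]))
    phen = pd.DataFrame(rows, columns=["animal", "cg", "value"])
    truth = SimulatedTruth(a_true, u_true, founder_freqs, cg_effects, phen)
    return phen, truth


def make_validation_split(
    ped: Pedigree, generation: np.ndarray, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli genotyping flags per generation; the genotyped animals of
    the final generation are the validation cohort.

    Returns (genotyped flags, validation flags) over pedigree order.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    probs = np.asarray(cfg.genotyping_prob)[generation]
    genotyped = rng.random(len(ped)) < probs
    validation = genotyped & (generation == generation.max())
    return genotyped, validation


def simulate(cfg: SimulationConfig) -> SimulatedData:
    """Run the full generator and bundle the dataset."""
    ped, generation, _sex = simulate_pedigree(cfg)
    dosages, p0 = drop_genotypes(ped, cfg)
    phen, truth = simulate_phenotypes(ped, dosages, p0, generation, cfg)
    genotyped, validation = make_validation_split(ped, generation, cfg)

    ids = np.asarray(ped.ids)
    gen_ids = [str(a) for a in ids[genotyped]]
    gm = GenotypeMatrix(dosages[genotyped], gen_ids)
    val_ids = [str(a) for a in ids[validation]]
    train_ids = [a for a in gen_ids if a not in set(val_ids)]
    return SimulatedData(cfg, ped, generation, gm, phen, truth, val_ids, train_ids)


def write_dataset(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Emit pedigree/genotype/phenotype/truth files plus a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.txt",
        "genotypes": outdir / "genotypes.txt",
        "phenotypes": outdir / "phenotypes.txt",
        "truth": outdir / "truth.txt",
        "validation": outdir / "validation_ids.txt",
        "config": outdir / "config.txt",
    }
    with open(paths["pedigree"], "w") as fh:
        for a, s, d in data.pedigree.records:
            fh.write(f"{a} {s} {d}\n")
    write_genotypes(data.genotypes, paths["genotypes"])
    data.phenotypes.to_csv(paths["phenotypes"], sep=" ", index=False, header=False)
    with open(paths["truth"], "w") as fh:
        for a, u in zip(data.pedigree.ids, data.truth.u_true):
            fh.write(f"{a} {float(u)!r}\n")
    paths["validation"].write_text("".join(f"{a}\n" for a in data.validation_ids))
    with open(paths["config"], "w") as fh:
        for key, val in asdict(data.config).items():
            fh.write(f"{key} {val}\n")
    return paths
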