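"""Validation design for indirect-prediction accuracies.

A benchmark ssGBLUP run with the complete data (validation animals
included) supplies reference GEBV and their accuracies. A reduced run
without the validation animals supplies the backsolved SNP effects; a
per-scenario run (full genotypes with direct or APY inverse, random
genotype subsets, core-only, high-accuracy-only, with or without pruning
to selected animals plus their progeny) supplies the MME inverse from
which the SNP PEC — and hence the IP accuracies — are computed. SNP
effects always come from the direct reduced run, mirroring interim
evaluations where effects are taken from the official evaluation.

Calibration is summarised by the Pearson correlation, the OLS regression
acc_bench = b0 + b1 * acc_ip, and mean/max absolute differences over the
validation animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .backsolve import IndirectPredictor
from .genomic import core_count_from_variance, select_core
from .mme import SingleStepGBLUP
from .pedigree import Pedigree
from .simulate import SimulatedData

__all__ = [
    "ScenarioConfig",
    "EvaluationReport",
    "calibration_metrics",
    "select_hacc",
    "prune_for_prog",
    "ScenarioSuite",
]

SCENARIO_NAMES = ("direct", "apy", "subset_n", "core", "hacc", "core_prog", "hacc_prog")


@dataclass
class ScenarioConfig:
    """One entry of the validation design.

    name : one of ``direct``, ``apy``, ``subset_n``, ``core``, ``hacc``,
        ``core_prog``, ``hacc_prog``.
    n_subset : subset size for ``subset_n`` (number of training genotypes
        entering the PEC computation).
    core_size : explicit APY-core / selection size; None applies the
        eigenvalue rule at ``core_threshold``.
    seed : seed for random subset / core draws.
    alpha : blending override for this scenario's evaluation (None keeps
        the suite default).
    """

    name: str
    n_subset: int | None = None
    core_size: int | None = None
    core_threshold: float = 0.99
    seed: int = 0
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}")


@dataclass
class EvaluationReport:
    """Benchmark-vs-indirect comparison over the validation animals."""

    scenario: str
    r_gebv_ip: float
    r: float
    b0: float
    b1: float
    mean_abs: float
    max_abs: float
    table: pd.DataFrame = field(repr=False)

    def summary(self) -> dict[str, float]:
        return {
            "scenario": self.scenario,
            "r_gebv_ip": self.r_gebv_ip,
            "r": self.r,
            "b0": self.b0,
            "b1": self.b1,
            "mean_abs": self.mean_abs,
            "max_abs": self.max_abs,
        }


def calibration_metrics(
    acc_bench: np.ndarray, acc_ip: np.ndarray
) -> tuple[float, float, float, float, float]:
    """(r, b0, b1, mean_abs, max_abs) of benchmark vs indirect accuracies.

    The regression is of the benchmark accuracy on the IP accuracy, so
    b1 < 1 flags inflation (overdispersion) of the IP accuracies.
    """
    a = np.asarray(acc_bench, float)
    b = np.asarray(acc_ip, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 accuracies")
    var_ip = b.var()
    if var_ip == 0:
        raise ValueError("zero variance in IP accuracies; calibration undefined")
    b1 = float(np.cov(a, b, ddof=0)[0, 1] / var_ip)
    b0 = float(a.mean() - b1 * b.mean())
    r = float(np.corrcoef(a, b)[0, 1])
    diff = np.abs(a - b)
    return r, b0, b1, float(diff.mean()), float(diff.max())


def select_hacc(acc_by_id: dict[str, float], n: int) -> list[str]:
    """Top-n animals by benchmark accuracy, ties broken by ascending
    position in the input ordering (deterministic)."""
    ids = list(acc_by_id)
    if n > len(ids):
        raise ValueError(f"n={n} exceeds the {len(ids)} candidate animals")
    order = sorted(range(len(ids)), key=lambda i: (-acc_by_id[ids[i]], i))
    return [ids[i] for i in sorted(order[:n])]


def prune_for_prog(
    selected_ids: list[str], pedigree: Pedigree, phenotypes: pd.DataFrame
) -> tuple[Pedigree, pd.DataFrame]:
    """Keep phenotypes of the selected animals and their direct progeny;
    prune the pedigree to the kept animals plus all their ancestors
    (ancestral closure, so every named parent stays present)."""
    selected = set(selected_ids)
    progeny = {a for a, s, d in pedigree.records if s in selected or d in selected}
    keep_phen = selected | progeny
    phen = phenotypes[phenotypes["animal"].astype(str).isin(keep_phen)].reset_index(drop=True)

    parents = {a: (s, d) for a, s, d in pedigree.records}
    kept: set[str] = set()
    stack = list(keep_phen)
    while stack:
        a = stack.pop()
        if a in kept or a not in parents:
            continue
        kept.add(a)
        for p in parents[a]:
            if p != "0":
                stack.append(p)
    records = [r for r in pedigree.records if r[0] in kept]
    return Pedigree(records), phen


class ScenarioSuite:
    """Runs the benchmark, the direct reduced evaluation, and any scenario.

    Parameters mirror :class:`~ipacc.mme.SingleStepGBLUP`; ``alpha`` is the
    default blending proportion of every evaluation in the suite.
    """

    def __init__(
        self,
        data: SimulatedData,
        *,
        sigma2_u: float | None = None,
        sigma2_e: float | None = None,
        alpha: float = 0.05,
        tune: bool = True,
        seed: int = 0,
    ) -> None:
        self.data = data
        self.sigma2_u = data.config.sigma2_u if sigma2_u is None else sigma2_u
        self.sigma2_e = data.config.sigma2_e if sigma2_e is None else sigma2_e
        self.alpha = alpha
        self.tune = tune
        self.seed = seed

    def _model(self, **overrides) -> SingleStepGBLUP:
        params = dict(
            sigma2_u=self.sigma2_u,
            sigma2_e=self.sigma2_e,
            alpha=self.alpha,
            tune=self.tune,
            seed=self.seed,
        )
        params.update(overrides)
        return SingleStepGBLUP(**params)

    @cached_property
    def benchmark(self) -> SingleStepGBLUP:
        """Full-data evaluation: validation animals' pedigree and genomic
        information restored (they still have no phenotypes)."""
        return self._model().fit(self.data.pedigree, self.data.genotypes, self.data.phenotypes)

    @cached_property
    def direct(self) -> SingleStepGBLUP:
        """Reduced evaluation without the validation animals (scenario S-direct)."""
        return self._model().fit(
            self.data.training_pedigree(), self.data.training_genotypes(), self.data.phenotypes
        )

    def benchmark_accuracies(self) -> np.ndarray:
        return self.benchmark.accuracy(self.data.validation_ids)

    def _pec_model(self, cfg: ScenarioConfig) -> SingleStepGBLUP:
        data = self.data
        alpha = self.alpha if cfg.alpha is None else cfg.alpha
        train_ids = list(data.training_genotyped_ids)
        ped = data.training_pedigree()
        phen = data.phenotypes

        if cfg.name == "direct":
            if cfg.alpha is None or cfg.alpha == self.alpha:
                return self.direct
            return self._model(alpha=alpha).fit(ped, data.training_genotypes(), phen)
        if cfg.name == "apy":
            return self._model(
                alpha=alpha,
                inverse="apy",
                core_size=cfg.core_size,
                core_threshold=cfg.core_threshold,
                seed=cfg.seed,
            ).fit(ped, data.training_genotypes(), phen)

        if cfg.name == "subset_n":
            if cfg.n_subset is None:
                raise ValueError("subset_n scenario needs n_subset")
            if cfg.n_subset > len(train_ids):
                raise ValueError(
                    f"subset of {cfg.n_subset} exceeds the {len(train_ids)} training genotypes"
                )
            subset = select_core(train_ids, cfg.n_subset, cfg.seed)
        elif cfg.name in ("core", "core_prog"):
            n_core = cfg.core_size or core_count_from_variance(self.direct.grm_.G, cfg.core_threshold)
            subset = select_core(train_ids, n_core, cfg.seed)
        elif cfg.name in ("hacc", "hacc_prog"):
            n = cfg.core_size or core_count_from_variance(self.direct.grm_.G, cfg.core_threshold)
            acc = self.benchmark.accuracy(train_ids)
            subset = select_hacc(dict(zip(train_ids, acc)), n)
        else:  # pragma: no cover
            raise AssertionError(cfg.name)

        gm = data.genotypes.subset(subset)
        if cfg.name.endswith("_prog"):
            ped, phen = prune_for_prog(subset, ped, phen)
        # subset PEC stays in the centering basis of the official run so it
        # describes the error of that run's SNP effects
        return self._model(alpha=alpha).fit(ped, gm, phen, freqs=self.direct.grm_.freqs)

    def run(self, cfg: ScenarioConfig) -> EvaluationReport:
        """Benchmark-vs-IP report for one scenario over validation animals."""
        bench = self.benchmark
        val_ids = self.data.validation_ids
        gebv = bench.gebv(val_ids)
        acc_bench = bench.accuracy(val_ids)

        effects_model = self.direct
        if cfg.alpha is not None and cfg.alpha != self.alpha:
            effects_model = self._pec_model(ScenarioConfig("direct", alpha=cfg.alpha))
        pec_model = effects_model if cfg.name == "direct" else self._pec_model(cfg)

        predictor = IndirectPredictor().fit(effects_model, pec_model=pec_model)
        val_gm = self.data.validation_genotypes()
        ip = predictor.predict(val_gm)
        acc_ip = predictor.accuracy(val_gm)

        r, b0, b1, mean_abs, max_abs = calibration_metrics(acc_bench, acc_ip)
        r_gebv_ip = float(np.corrcoef(gebv, ip)[0, 1])
        table = pd.DataFrame(
            {"animal": val_ids, "gebv": gebv, "ip": ip, "acc_gebv": acc_bench, "acc_ip": acc_ip}
        )
        return EvaluationReport(cfg.name, r_gebv_ip, r, b0, b1, mean_abs, max_abs, table)

    def blending_sweep(self, alphas: list[float]) -> pd.DataFrame:
        """Direct scenario repeated at each blending proportion.

        The benchmark stays at the suite default; each row reports the
        calibration metrics (alpha, r, b0, b1)."""
        rows = []
        for a in alphas:
            if not 0.0 <= a < 0.5:
                raise ValueError("blending proportions must lie in [0, 0.5)")
            rep = self.run(ScenarioConfig("direct", alpha=a))
            rows.append({"alpha": a, "r": rep.r, "b0": rep.b0, "b1": rep.b1})
        return pd.DataFrame(rows)
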