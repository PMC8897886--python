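"""Seeded synthetic-data generators with known ground truth.

Every generator records the planted truth (module labels, subgroup
labels, log hazard ratio, feature effects) so downstream tests can
score recovery without re-deriving it. A single seed is fanned out to
independent child streams per generator, so adding a generator never
perturbs previously generated fixtures.

The expression generator draws from a block-exchangeable correlation
model: gene g in module m is

    x_g = sqrt(b) * u + sqrt(w - b) * v_m + sqrt(1 - w) * e_g

with shared factor u, module factor v_m, and idiosyncratic noise e_g,
giving within-module correlation w and between-module correlation b
by construction (positive semi-definite for any 0 <= b <= w < 1).
Survival times are exponential with the group-1 hazard multiplied by
exp(log_hr) and independent exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CATEGORICAL, CONTINUOUS, ClinicalTable, ExpressionMatrix


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every generated dataset."""

    module_labels: pd.Series | None = None  # gene -> planted module (int)
    subgroup_labels: pd.Series | None = None  # sample -> planted group (int)
    log_hr: float | None = None
    feature_specs: list[dict] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        """Plain-text key-value sidecar."""
        with open(path, "w") as fh:
            if self.log_hr is not None:
                fh.write(f"log_hr\t{self.log_hr!r}\n")
            if self.module_labels is not None:
                for g, m in self.module_labels.items():
                    fh.write(f"module\t{g}\t{m}\n")
            if self.subgroup_labels is not None:
                for s, g in self.subgroup_labels.items():
                    fh.write(f"subgroup\t{s}\t{g}\n")
            for spec in self.feature_specs:
                fh.write(f"feature\t{spec!r}\n")


def _rng(seed: int | np.random.Generator, stream: int) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), stream])))


def make_modular_expression(
    n_genes: int = 60,
    n_samples: int = 200,
    k_modules: int = 3,
    within_r: float = 0.8,
    between_r: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Expression matrix with planted co-expression modules.

    Genes are split evenly (contiguously) into ``k_modules`` blocks with
    exchangeable correlation ``within_r`` inside a block and
    ``between_r`` across blocks.
    """
    if not 0 <= between_r <= within_r < 1:
        raise ValueError(
            f"infeasible correlation structure: need 0 <= between_r <= within_r < 1 "
            f"(got between_r={between_r}, within_r={within_r})"
        )
    if k_modules < 1 or n_genes < k_modules:
        raise ValueError("need at least one gene per module")
    rng = _rng(seed, 1)
    modules = np.repeat(np.arange(k_modules), int(np.ceil(n_genes / k_modules)))[:n_genes]
    shared = rng.standard_normal(n_samples)
    module_factor = rng.standard_normal((k_modules, n_samples))
    noise = rng.standard_normal((n_genes, n_samples))
    x = (
        np.sqrt(between_r) * shared
        + np.sqrt(within_r - between_r) * module_factor[modules]
        + np.sqrt(1.0 - within_r) * noise
    )
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids))
    truth = SimulationTruth(module_labels=pd.Series(modules, index=gene_ids))
    return expr, truth


def make_subgrouped_expression(
    n_genes: int = 20,
    n_samples: int = 60,
    k_groups: int = 2,
    shift_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Expression with planted sample subgroups (mean-shifted driver genes).

    Samples are split evenly into ``k_groups``; every gene's mean is
    shifted by ``shift_sd`` standard deviations per group index, on
    unit-variance noise.
    """
    if k_groups < 2 or n_samples < 2 * k_groups:
        raise ValueError("need at least 2 groups and 2 samples per group")
    rng = _rng(seed, 2)
    groups = np.repeat(np.arange(k_groups), int(np.ceil(n_samples / k_groups)))[:n_samples]
    x = rng.standard_normal((n_genes, n_samples)) + shift_sd * groups[None, :]
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids))
    truth = SimulationTruth(subgroup_labels=pd.Series(groups, index=sample_ids))
    return expr, truth


def make_survival(
    labels: Sequence[int],
    log_hr: float = np.log(2.0),
    baseline_rate: float = 0.1,
    censor_rate: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with a known group hazard ratio.

    Group-1 samples have hazard ``baseline_rate * exp(log_hr)``;
    censoring is an independent exponential with ``censor_rate``
    (0 disables censoring). Returns a frame with ``time`` and ``event``
    columns indexed like ``labels``.
    """
    labels = pd.Series(labels)
    lab = labels.to_numpy()
    if not set(np.unique(lab)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if baseline_rate <= 0 or censor_rate < 0:
        raise ValueError("rates must be positive (censor_rate may be 0)")
    n = len(lab)
    # expected events under competing exponentials: rate / (rate + censor) per arm
    rates = baseline_rate * np.exp(log_hr * lab)
    expected_events = float(np.sum(rates / (rates + censor_rate)))
    if expected_events < 1:
        raise ValueError(
            f"censor_rate={censor_rate} leaves {expected_events:.2f} expected events (< 1)"
        )
    rng = _rng(seed, 3)
    t_event = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=labels.index)


def make_clinical(
    subgroup_labels: Sequence[int],
    specs: list[dict],
    seed: int = 0,
) -> tuple[ClinicalTable, SimulationTruth]:
    """Clinical features with known distributions and per-group effects.

    Each spec is a dict: ``{"name", "dist": normal|lognormal|categorical,
    ...}``. Normal/lognormal take ``mean``, ``sd``, and ``shift`` (mean
    shift in SD units per group index, on the normal scale); categorical
    takes ``levels`` and per-group probability vectors ``probs`` (one
    row per group, or a single shared vector).
    """
    labels = pd.Series(subgroup_labels)
    lab = labels.to_numpy()
    n = len(lab)
    rng = _rng(seed, 4)
    data: dict[str, np.ndarray] = {}
    types: dict[str, str] = {}
    for spec in specs:
        name, dist = spec["name"], spec["dist"]
        if dist in ("normal", "lognormal"):
            mean = spec.get("mean", 0.0)
            sd = spec.get("sd", 1.0)
            shift = spec.get("shift", 0.0)
            z = rng.standard_normal(n) * sd + mean + shift * sd * lab
            data[name] = np.exp(z) if dist == "lognormal" else z
            types[name] = CONTINUOUS
        elif dist == "categorical":
            levels = list(spec["levels"])
            probs = np.atleast_2d(np.asarray(spec["probs"], dtype=float))
            if probs.shape[0] == 1:
                probs = np.repeat(probs, lab.max() + 1, axis=0)
            draws = np.empty(n, dtype=object)
            for g in np.unique(lab):
                idx = np.flatnonzero(lab == g)
                draws[idx] = rng.choice(levels, size=len(idx), p=probs[g])
            data[name] = draws
            types[name] = CATEGORICAL
        else:
            raise ValueError(f"unknown distribution {dist!r} for feature {name!r}")
    table = ClinicalTable(pd.DataFrame(data, index=labels.index.astype(str)), types)
    truth = SimulationTruth(subgroup_labels=labels, feature_specs=list(specs))
    return table, truth


def make_gene_sets(gene_ids: Sequence[str], n_sets: int = 5, seed: int = 0) -> dict:
    """Random gene sets over the given universe (for enrichment fixtures)."""
    from .io import GeneSetCollection

    rng = _rng(seed, 5)
    gene_ids = list(gene_ids)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(5, max(6, len(gene_ids) // 3)))
        members = tuple(rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False))
        sets[f"SET{i + 1:03d}"] = (f"synthetic set {i + 1}", members)
    return GeneSetCollection(sets)
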