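"""Synthetic multi-study two-cohort expression data with a planted signature.

The generator emulates the regime of a multi-study postmortem-brain
microarray compendium at desk scale: several independent case/control
studies measure the same gene universe; a shared subset of genes is truly
differentially expressed, but each study observes that signal attenuated by
a study-specific factor, shifted by study-specific batch effects, and
buried in residual noise.  This is exactly the setting in which naive
per-study selectors produce irreproducible signatures.

Model (all on the log2 scale)
-----------------------------
* Baseline: gene g has a study-independent baseline ``b_g`` drawn from a
  log-normal intensity distribution, i.e. normal on the log2 scale
  (default mean 7, sd 1.5 — typical microarray log2 intensities).
* Signal: the planted signature genes are shifted in cases by
  ``effect_size * a_s`` where ``a_s ~ Uniform(effect_attenuation)`` is
  drawn once per study; half the signature is up-, half down-regulated.
* Batch: each (study, gene) pair receives a location shift
  ``N(0, batch_shift_sd)`` applied to all samples of the study.
* Noise: i.i.d. ``N(0, noise_sd)`` per entry, optionally equicorrelated in
  consecutive gene blocks of size ``correlation_block_size`` with
  correlation ``correlation_rho``.
* Cohort heterogeneity: a fraction ``label_noise`` of each cohort's
  samples express the *other* cohort's signal profile while keeping their
  label (diagnostic misclassification).  This caps the achievable
  classification accuracy below 1, matching the sub-ceiling accuracies
  observed in real case/control brain cohorts.
* Measurement artifacts: a fraction ``outlier_fraction`` of matrix
  entries receive signed heavy-tailed spikes of ``U(outlier_scale)``
  noise SDs — the sparse single-entry outlier pattern typical of
  microarray intensities.

Per-study seeds are derived deterministically from the master seed via
``numpy.random.SeedSequence([seed, study_index + 1])``, so one integer
reproduces an entire multi-study experiment; the planted signature itself
depends only on the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_study", "simulate_multistudy"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic benchmark.

    Defaults define the desk-scale benchmark used throughout: 4 studies of
    60 samples (30 cases, 30 controls) over 500 genes with 20 planted
    signal genes whose per-study realized effect is a 0.7-1.0 log2-unit
    case/control shift against unit residual noise.
    """

    n_genes: int = 500
    n_signal_genes: int = 20
    n_case: int = 30
    n_control: int = 30
    n_studies: int = 4
    effect_size: float = 1.0
    effect_attenuation: tuple[float, float] = (0.7, 1.0)
    batch_shift_sd: float = 0.3
    noise_sd: float = 1.0
    label_noise: float = 0.1
    outlier_fraction: float = 0.01
    outlier_scale: tuple[float, float] = (2.0, 6.0)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    correlation_block_size: int | None = None
    correlation_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must be <= n_genes")
        for name in ("n_genes", "n_signal_genes", "n_case", "n_control", "n_studies"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.effect_attenuation
        if not (0 <= lo <= hi):
            raise ValueError("effect_attenuation must be an ordered non-negative range")
        if self.correlation_block_size is not None and not (0 <= self.correlation_rho < 1):
            raise ValueError("correlation_rho must be in [0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for one simulated study."""

    signature: frozenset[str]
    realized_effects: pd.DataFrame = field(repr=False)  # gene, effect (log2 shift)
    attenuation: float = 1.0


def _gene_ids(cfg: SimulationConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]


def _universe(cfg: SimulationConfig) -> tuple[list[str], list[str], np.ndarray]:
    """Gene ids, planted signature and per-gene baselines.

    Drawn from ``SeedSequence([seed, 0])`` so they depend only on the
    master seed and are shared by every study.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    genes = _gene_ids(cfg)
    signature = sorted(rng.choice(genes, size=cfg.n_signal_genes, replace=False))
    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    return genes, signature, baselines


def _planted_signature(cfg: SimulationConfig) -> list[str]:
    """Signal genes, a deterministic function of the master seed only."""
    return _universe(cfg)[1]


def _correlated_noise(rng: np.random.Generator, cfg: SimulationConfig, shape: tuple[int, int]) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, size=shape)
    if cfg.correlation_block_size and cfg.correlation_rho > 0:
        m = cfg.correlation_block_size
        rho = cfg.correlation_rho
        for start in range(0, shape[0], m):
            stop = min(start + m, shape[0])
            shared = rng.normal(0.0, 1.0, size=(1, shape[1]))
            noise[start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise[start:stop]
    return cfg.noise_sd * noise


def simulate_study(
    cfg: SimulationConfig, study_index: int = 0
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Simulate one two-cohort study; deterministic given (cfg.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, study_index + 1]))
    genes, signature, baselines = _universe(cfg)
    n = cfg.n_case + cfg.n_control

    lo, hi = cfg.effect_attenuation
    attenuation = float(rng.uniform(lo, hi))
    # alternate up/down regulation across the sorted signature
    signs = {g: (1.0 if k % 2 == 0 else -1.0) for k, g in enumerate(signature)}
    effects = np.zeros(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in signature:
        effects[gene_pos[g]] = signs[g] * cfg.effect_size * attenuation

    batch = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_genes)
    noise = _correlated_noise(rng, cfg, (cfg.n_genes, n))

    # cohort label noise: a fraction of "cases" lack the expression signal
    # and the same fraction of "controls" carry it (diagnostic heterogeneity)
    signal_cols = np.zeros(n, dtype=bool)
    signal_cols[: cfg.n_case] = True
    n_flip_case = round(cfg.label_noise * cfg.n_case)
    n_flip_ctrl = round(cfg.label_noise * cfg.n_control)
    if n_flip_case:
        signal_cols[rng.choice(cfg.n_case, n_flip_case, replace=False)] = False
    if n_flip_ctrl:
        signal_cols[cfg.n_case + rng.choice(cfg.n_control, n_flip_ctrl, replace=False)] = True

    x = baselines[:, None] + batch[:, None] + noise
    x[:, signal_cols] += effects[:, None]

    # heavy-tailed measurement artifacts: sparse large spikes on single
    # entries, the classic microarray outlier pattern
    if cfg.outlier_fraction > 0:
        n_spikes = round(cfg.outlier_fraction * x.size)
        if n_spikes:
            flat = rng.choice(x.size, size=n_spikes, replace=False)
            lo_s, hi_s = cfg.outlier_scale
            spikes = rng.uniform(lo_s, hi_s, size=n_spikes) * cfg.noise_sd
            spikes *= rng.choice([-1.0, 1.0], size=n_spikes)
            x.flat[flat] += spikes

    study_id = f"S{study_index + 1}"
    samples = [f"{study_id}_case{i + 1:02d}" for i in range(cfg.n_case)] + [
        f"{study_id}_ctrl{i + 1:02d}" for i in range(cfg.n_control)
    ]
    labels = pd.Series([1] * cfg.n_case + [0] * cfg.n_control, index=samples)
    ds = ExpressionDataset(
        matrix=pd.DataFrame(x, index=genes, columns=samples),
        labels=labels,
        study_id=study_id,
        is_log_scale=True,
    )
    truth = SimulationTruth(
        signature=frozenset(signature),
        realized_effects=pd.DataFrame(
            {"gene": signature, "effect": [effects[gene_pos[g]] for g in signature]}
        ),
        attenuation=attenuation,
    )
    return ds, truth


def simulate_multistudy(cfg: SimulationConfig) -> list[tuple[ExpressionDataset, SimulationTruth]]:
    """Simulate ``cfg.n_studies`` studies sharing one planted signature."""
    if cfg.n_studies < 2:
        raise ValueError("simulate_multistudy needs n_studies >= 2")
    return [simulate_study(cfg, i) for i in range(cfg.n_studies)]


def with_overrides(cfg: SimulationConfig, **kwargs) -> SimulationConfig:
    """Convenience: a copy of ``cfg`` with the given fields replaced."""
    return replace(cfg, **kwargs)
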