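"""Synthetic cohorts with known ground truth.

The patient-level expression and survival data behind the published PCNSL
formulas are not deposited, so every downstream stage is validated against
cohorts generated here with the statistical structure the analysis assumes:

* Expression: log-normal FPKM whose log-scale Gaussian is equi-correlated
  within each panel's variant block (a one-common-factor copula per block),
  emulating co-expressed immune-checkpoint modules.  A variant shared by two
  panels (e.g. CD4-001) is generated once, in the first panel's block.
* Survival: proportional hazards with a constant (exponential) baseline.
  The log-hazard is ``beta`` per 1 SD of the designated driver panel's score;
  censoring is an independent exponential clock.

All randomness flows through one :func:`numpy.random.default_rng` (PCG64)
instance seeded from ``SimulationConfig.seed``; identical configs give
identical cohorts on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ClinicalTable, Cohort, ExpressionMatrix, ScorePanel, load_panels
from .exceptions import ConfigError, ValidationError
from .scoring import compute_score

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_survival",
    "simulate_cohort",
    "write_cohort",
]


def _default_panels() -> list[ScorePanel]:
    return list(load_panels("pcnsl2019").values())


@dataclass
class SimulationConfig:
    """Generator parameters.

    Defaults describe a realistic PCNSL-like cohort: 31 patients, moderate
    within-module co-expression, median FPKM ~ e (log-normal(1, 1)), a
    baseline hazard of 1e-3 per day (median OS ~ 23 months), and a censoring
    rate of 5e-4 per day (roughly a third of subjects censored).
    """

    n_samples: int = 31
    panels: list[ScorePanel] = field(default_factory=_default_panels)
    block_correlation: float = 0.4
    fpkm_log_mean: float = 1.0
    fpkm_log_sd: float = 1.0
    beta: float = np.log(2.0)
    driver_panel: str = "Inhibitory"
    #: optional multi-driver spec ``{panel name: beta}``; overrides
    #: ``beta``/``driver_panel`` (e.g. Th1 protective + Th2 harmful).
    drivers: dict[str, float] | None = None
    baseline_hazard: float = 1e-3
    censor_rate: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigError("n_samples must be >= 4")
        if not self.panels:
            raise ConfigError("at least one panel is required")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ConfigError("block_correlation must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if not all(np.isfinite(b) for b in self.driver_betas().values()):
            raise ConfigError("driver betas must be finite")

    def driver_betas(self) -> dict[str, float]:
        """Effective ``{panel: log-hazard per SD}`` map."""
        if self.drivers is not None:
            return dict(self.drivers)
        return {self.driver_panel: float(self.beta)}

    def block_assignment(self) -> dict[str, str]:
        """Variant -> owning panel block (first panel wins for shared variants)."""
        assignment: dict[str, str] = {}
        for panel in self.panels:
            for v in panel.variant_ids:
                assignment.setdefault(v, panel.name)
        return assignment


@dataclass
class GroundTruth:
    """What the generator actually used, for parameter-recovery checks."""

    drivers: dict[str, float]     # panel -> true log-hazard per SD of its score
    scores: pd.DataFrame          # samples x driver panels, formula scores
    z: pd.DataFrame               # samples x driver panels, cohort z-scores
    block_assignment: dict[str, str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.z):
            raise ValidationError("ground-truth score/z frames have mismatched lengths")

    @property
    def driver_panel(self) -> str:
        """Single-driver convenience accessor."""
        return next(iter(self.drivers))

    @property
    def beta(self) -> float:
        return self.drivers[self.driver_panel]

    @property
    def driver_scores(self) -> pd.Series:
        return self.scores[self.driver_panel]

    @property
    def driver_z(self) -> pd.Series:
        return self.z[self.driver_panel]


def simulate_expression(cfg: SimulationConfig) -> ExpressionMatrix:
    """Draw a variant-by-sample FPKM matrix.

    One row per variant in the union of ``cfg.panels`` (de-duplicated,
    first-appearance order).  Within each block the log-FPKM Gaussian has
    pairwise correlation ``block_correlation``, realised through a shared
    per-sample factor: ``z = sqrt(rho) * u_block + sqrt(1-rho) * eps``.
    """
    rng = np.random.default_rng(cfg.seed)
    assignment = cfg.block_assignment()
    variants = list(assignment)
    n = cfg.n_samples
    rho = cfg.block_correlation
    z = np.empty((len(variants), n))
    blocks: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        blocks.setdefault(assignment[v], []).append(i)
    for panel in cfg.panels:
        rows = blocks.get(panel.name)
        if not rows:
            continue
        common = rng.standard_normal(n)
        eps = rng.standard_normal((len(rows), n))
        z[rows] = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * eps
    fpkm = np.exp(cfg.fpkm_log_mean + cfg.fpkm_log_sd * z)
    samples = [f"S{i+1:03d}" for i in range(n)]
    return ExpressionMatrix(pd.DataFrame(fpkm, index=variants, columns=samples))


def simulate_survival(
    expr: ExpressionMatrix, cfg: SimulationConfig
) -> tuple[ClinicalTable, GroundTruth]:
    """Draw survival outcomes whose hazard follows the driver-panel score.

    ``T_event ~ Exp(baseline_hazard * exp(beta * z))`` with ``z`` the cohort
    z-score (ddof=1) of the driver score; ``T_censor ~ Exp(censor_rate)``
    (infinite when the rate is 0, i.e. no censoring).  The RNG stream is
    seeded with ``cfg.seed + 1`` so expression and survival draws never
    overlap even though both derive from one config.
    """
    betas = cfg.driver_betas()
    panel_map = {p.name: p for p in cfg.panels}
    scores = {}
    zs = {}
    log_rr = np.zeros(cfg.n_samples)
    for name, beta in betas.items():
        driver = panel_map.get(name)
        if driver is None:
            raise ConfigError(f"driver panel {name!r} not in config panels")
        missing = [v for v in driver.variant_ids if v not in expr.data.index]
        if missing:
            raise ValidationError(f"driver-panel variants missing from expression: {missing}")
        score = compute_score(expr, driver).scores
        sd = score.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"driver score {name!r} is constant; cannot standardize")
        z = (score - score.mean()) / sd
        scores[name] = score
        zs[name] = z
        log_rr += beta * z.to_numpy()
    rng = np.random.default_rng(cfg.seed + 1)
    rate = cfg.baseline_hazard * np.exp(log_rr)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, size=cfg.n_samples)
    else:
        t_cens = np.full(cfg.n_samples, np.inf)
    os_days = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    clin = ClinicalTable(
        pd.DataFrame({"os_days": os_days, "event": event}, index=expr.sample_ids)
    )
    truth = GroundTruth(
        drivers=betas,
        scores=pd.DataFrame(scores),
        z=pd.DataFrame(zs),
        block_assignment=cfg.block_assignment(),
        seed=cfg.seed,
    )
    return clin, truth


def simulate_cohort(cfg: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Expression + survival in one call (samples already aligned)."""
    expr = simulate_expression(cfg)
    clin, truth = simulate_survival(expr, cfg)
    return Cohort(expr, clin), truth


def write_cohort(cohort: Cohort, truth: GroundTruth, directory) -> dict[str, str]:
    """Emit a simulated cohort as the on-disk formats the readers accept.

    Writes ``expression.tsv``, ``clinical.tsv`` and ``ground_truth.json``
    (drivers, per-sample scores/z, block assignment, seed) into
    ``directory`` and returns the path map.
    """
    import json
    from pathlib import Path

    from .data_model import write_clinical, write_expression

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(directory / "expression.tsv"),
        "clinical": str(directory / "clinical.tsv"),
        "ground_truth": str(directory / "ground_truth.json"),
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    payload = {
        "drivers": truth.drivers,
        "scores": {c: truth.scores[c].round(10).to_dict() for c in truth.scores},
        "z": {c: truth.z[c].round(10).to_dict() for c in truth.z},
        "block_assignment": truth.block_assignment,
        "seed": truth.seed,
    }
    Path(paths["ground_truth"]).write_text(json.dumps(payload, indent=2) + "\n")
    return paths
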