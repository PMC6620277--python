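"""Apply score-panel formulas to expression matrices.

A panel score is the weighted sum ``score(s) = sum_v w(v) * FPKM(v, s)``:
linear in expression, non-negative whenever the weights and FPKM are.  The
published formulas are stated directly over raw FPKM, so that is the default;
``log2p1=True`` applies ``log2(FPKM + 1)`` first for sensitivity analyses.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Cohort, ExpressionMatrix, ScorePanel
from .exceptions import ValidationError

__all__ = ["ScoreVector", "compute_score", "compute_all_scores", "standardize"]


def panel_checksum(panel: ScorePanel) -> str:
    """Stable hex digest of a panel's (variant, coefficient) pairs."""
    blob = ";".join(f"{v}:{w!r}" for v, w in sorted(panel.weights.items()))
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class ScoreVector:
    """Per-sample panel scores plus formula provenance."""

    panel: str
    scores: pd.Series
    checksum: str
    transform: str = "raw"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValidationError(f"non-finite score in panel {self.panel!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_numpy(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def compute_score(
    expr: ExpressionMatrix,
    panel: ScorePanel,
    *,
    impute_zero: bool = False,
    log2p1: bool = False,
) -> ScoreVector:
    """Score every sample of ``expr`` with one panel.

    Missing panel variants are an error unless ``impute_zero`` is set, in
    which case they contribute 0 FPKM (with a warning): silently zeroing
    would otherwise corrupt scores.
    """
    missing = [v for v in panel.variant_ids if v not in expr.data.index]
    if missing and not impute_zero:
        raise ValidationError(
            f"panel {panel.name!r}: variants missing from expression matrix: "
            f"{', '.join(missing)} (pass impute_zero=True to treat as 0 FPKM)"
        )
    if missing:
        warnings.warn(
            f"panel {panel.name!r}: imputing FPKM 0 for missing variants {missing}",
            UserWarning,
            stacklevel=2,
        )
    present = [v for v in panel.variant_ids if v not in missing]
    block = expr.data.loc[present]
    if log2p1:
        block = np.log2(block + 1.0)
    weights = np.array([panel.weights[v] for v in present])
    scores = pd.Series(weights @ block.to_numpy(), index=expr.data.columns, name=panel.name)
    return ScoreVector(
        panel=panel.name,
        scores=scores,
        checksum=panel_checksum(panel),
        transform="log2p1" if log2p1 else "raw",
    )


def compute_all_scores(
    cohort: Cohort | ExpressionMatrix,
    panels: dict[str, ScorePanel],
    **kwargs,
) -> dict[str, ScoreVector]:
    """Score a cohort with every panel; sample order follows the cohort."""
    expr = cohort.expression if isinstance(cohort, Cohort) else cohort
    return {name: compute_score(expr, panel, **kwargs) for name, panel in panels.items()}


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each variant row by its across-sample SD (ddof=1).

    Rows with zero SD cannot be scaled; they are left unchanged, reported via
    a :class:`UserWarning`, and listed in ``metadata['zero_sd_variants']`` of
    the returned matrix.  Idempotent: standardized rows have unit SD.
    """
    data = expr.data.copy()
    sd = data.std(axis=1, ddof=1)
    zero = sd.index[(sd == 0) | ~np.isfinite(sd)].tolist()
    if zero:
        warnings.warn(
            f"standardize: zero-SD rows left unscaled: {zero}", UserWarning, stacklevel=2
        )
    scale = sd.copy()
    scale[zero] = 1.0
    out = ExpressionMatrix(
        data.div(scale, axis=0),
        transcript_ids=dict(expr.transcript_ids),
        metadata={**expr.metadata, "zero_sd_variants": zero},
    )
    return out
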