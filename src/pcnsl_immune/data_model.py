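"""Typed containers and TSV/YAML readers for expression, clinical and panel data.

The in-memory containers are thin wrappers around :class:`pandas.DataFrame` /
:class:`pandas.Series` that validate domain invariants on construction:

* :class:`ExpressionMatrix` — transcript variants (rows, labels like
  ``PDCD1-002``) by samples (columns), values are non-negative FPKM.
* :class:`ClinicalTable` — per-sample overall-survival time in days, a binary
  deceased/censored event flag, and arbitrary extra covariates.
* :class:`ScorePanel` — an ordered ``variant -> coefficient`` map, the weights
  of one prognosis-score formula.
* :class:`Cohort` — an expression matrix and clinical table over the same
  samples in the same order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import AlignmentError, ConfigError, FormatError, ValidationError
from .panels import BUILTIN_PANELS

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "ScorePanel",
    "Cohort",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "load_panels",
    "write_panels",
    "align_cohort",
]

logger = logging.getLogger(__name__)

#: ``GENE-NNN`` with a zero-padded integer suffix, e.g. ``PDCD1-001``.
VARIANT_LABEL_RE = re.compile(r"^[A-Za-z0-9]+-\d{3}$")


def _check_unique(labels, what: str) -> None:
    seen: set = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionMatrix:
    """Variant-by-sample FPKM matrix.

    Parameters
    ----------
    data
        DataFrame indexed by transcript-variant label with sample columns.
        All values must be finite and non-negative.
    transcript_ids
        Optional map variant label -> Ensembl transcript ID (metadata only).
    metadata
        Free-form provenance notes (e.g. which rows were left unscaled
        during standardization).
    """

    data: pd.DataFrame
    transcript_ids: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "variant ID")
        _check_unique(self.data.columns, "sample ID")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at variant {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression value {values[r, c]} at variant "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_variants(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data.loc[:, list(samples)].copy(),
            transcript_ids=dict(self.transcript_ids),
            metadata=dict(self.metadata),
        )


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus optional covariates.

    ``data`` is indexed by sample ID with columns ``os_days`` (positive) and
    ``event`` (1 = deceased, 0 = censored); any further columns are treated
    as covariates.
    """

    data: pd.DataFrame

    REQUIRED = ("os_days", "event")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        _check_unique(self.data.index, "sample ID")
        os_days = self.data["os_days"].to_numpy(dtype=float)
        if not np.all(np.isfinite(os_days)) or (os_days <= 0).any():
            bad = self.data.index[~(np.isfinite(os_days) & (os_days > 0))][0]
            raise ValidationError(f"os_days must be finite and > 0 (sample {bad!r})")
        event = self.data["event"].to_numpy(dtype=float)
        if not np.isin(event, (0.0, 1.0)).all():
            bad = self.data.index[~np.isin(event, (0.0, 1.0))][0]
            raise ValidationError(f"event must be 0 or 1 (sample {bad!r})")
        self.data = self.data.assign(
            os_days=os_days.astype(float), event=event.astype(int)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_days(self) -> np.ndarray:
        return self.data["os_days"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def covariates(self) -> pd.DataFrame:
        extra = [c for c in self.data.columns if c not in self.REQUIRED]
        return self.data[extra]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def subset_samples(self, samples: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


@dataclass(frozen=True, eq=False)
class ScorePanel:
    """Named prognosis-score formula: ordered ``variant -> coefficient`` map.

    ``provenance`` records how a derived panel was obtained (method, SDs,
    seeds); it is empty for the built-in published formulas.
    """

    name: str
    weights: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            raise ConfigError(f"panel {self.name!r} has no variants")
        clean: dict[str, float] = {}
        for variant, coef in self.weights.items():
            try:
                val = float(coef)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"panel {self.name!r}: non-numeric coefficient {coef!r} "
                    f"for {variant!r}"
                ) from None
            if not np.isfinite(val):
                raise ConfigError(f"panel {self.name!r}: non-finite coefficient for {variant!r}")
            if not VARIANT_LABEL_RE.match(str(variant)):
                raise ConfigError(
                    f"panel {self.name!r}: invalid variant label {variant!r} "
                    "(expected GENE-NNN)"
                )
            clean[str(variant)] = val
        object.__setattr__(self, "weights", clean)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.weights)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class Cohort:
    """Expression + clinical data over an identical, identically ordered sample set."""

    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise AlignmentError(
                "cohort expression and clinical sample orders differ; "
                "use align_cohort()"
            )
        if self.expression.n_samples < 2:
            raise ValidationError("a cohort needs at least 2 samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-separated variant-by-sample FPKM matrix.

    First row holds sample IDs, first column variant labels.  An optional
    second column of Ensembl transcript IDs (``ENST...``) is stored as
    metadata rather than expression.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"expression file {path} has no data rows")
    df.index.name = None
    transcript_ids: dict[str, str] = {}
    first = df.columns[0]
    if df[first].astype(str).str.startswith("ENST").all():
        transcript_ids = dict(zip(df.index, df[first].astype(str)))
        df = df.drop(columns=[first])
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = df.index[converted.isna()][0]
            raise FormatError(
                f"non-numeric expression value {df.loc[row, col]!r} at variant "
                f"{row!r}, sample {col!r}"
            )
        numeric[col] = converted
    return ExpressionMatrix(numeric, transcript_ids=transcript_ids)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write an :class:`ExpressionMatrix` as the TSV ``read_expression`` accepts."""
    df = expr.data
    if expr.transcript_ids:
        df = df.copy()
        df.insert(0, "transcript_id", [expr.transcript_ids.get(v, "") for v in df.index])
    df.to_csv(path, sep="\t", index_label="variant")


def read_clinical(path) -> ClinicalTable:
    """Read a tab-separated clinical table with columns sample, os_days, event.

    Unknown columns are retained as covariates.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse clinical file {path}: {exc}") from exc
    if "sample" not in df.columns:
        raise FormatError("clinical table missing required column 'sample'")
    df = df.set_index("sample")
    df.index.name = None
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample")


def load_panels(source: str = "pcnsl2019") -> dict[str, ScorePanel]:
    """Load score panels from a built-in fixture name or a YAML/JSON file.

    ``"pcnsl2019"`` returns the four published PCNSL prognosis formulas
    (Th1, Th2, Stimulatory, Inhibitory) with their printed coefficients.
    A file must map ``panel name -> {variant: coefficient}``.
    """
    if source in BUILTIN_PANELS:
        return {
            name: ScorePanel(name, dict(weights))
            for name, weights in BUILTIN_PANELS[source].items()
        }
    try:
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(
            f"{source!r} is neither a built-in fixture "
            f"({', '.join(BUILTIN_PANELS)}) nor a readable file"
        ) from None
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"panel config {source} must map panel names to weights")
    panels: dict[str, ScorePanel] = {}
    for name, weights in raw.items():
        if not isinstance(weights, dict) or not weights:
            raise ConfigError(f"panel {name!r} in {source} is empty or not a mapping")
        panels[str(name)] = ScorePanel(str(name), weights)
    return panels


def write_panels(panels: dict[str, ScorePanel], path) -> None:
    payload = {name: dict(p.weights) for name, p in panels.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def align_cohort(expr: ExpressionMatrix, clin: ClinicalTable) -> Cohort:
    """Restrict both tables to their common samples, lexicographically ordered.

    Dropped samples are reported through the module logger.  Raises
    :class:`AlignmentError` when the tables share no samples.
    """
    common = sorted(set(expr.sample_ids) & set(clin.sample_ids))
    if not common:
        raise AlignmentError("expression and clinical tables share no sample IDs")
    dropped_expr = sorted(set(expr.sample_ids) - set(common))
    dropped_clin = sorted(set(clin.sample_ids) - set(common))
    if dropped_expr:
        logger.info("align_cohort: dropping expression-only samples %s", dropped_expr)
    if dropped_clin:
        logger.info("align_cohort: dropping clinical-only samples %s", dropped_clin)
    return Cohort(expr.subset_samples(common), clin.subset_samples(common))
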