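"""Patient subgrouping: median splits, Th-1/Th-2 quadrants, optimal cutoffs.

Tie rule: a value exactly equal to the split threshold is labelled ``low``,
which keeps the two groups deterministic and near-equal in size.

The maximally selected cutoff scans the midpoints between consecutive
distinct sorted values whose induced groups both satisfy a minimum-size
fraction, and keeps the one maximizing the two-sample log-rank statistic.
The log-rank p-value at the selected cutoff is optimistically biased (the
cutoff was chosen to maximize the statistic); it is reported with an explicit
flag, and a seeded permutation-adjusted p-value is available on request.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ClinicalTable, ExpressionMatrix
from .exceptions import ValidationError
from .scoring import ScoreVector
from .survival import (
    LogrankResult,
    SurvivalComparison,
    compare_groups,
    km_estimate,
    logrank_test,
    one_way_anova,
)

__all__ = [
    "StratificationRule",
    "GroupAssignment",
    "median_split",
    "quadrant_split",
    "quadrant_hazards",
    "optimal_cutoff",
    "overlay_by_quadrant",
]

QUADRANT_LABELS = ("Th1hiTh2hi", "Th1hiTh2lo", "Th1loTh2hi", "Th1loTh2lo")


@dataclass(frozen=True)
class StratificationRule:
    kind: str                       # median | cutoff | quadrant
    thresholds: tuple[float, ...]   # 1 threshold, or 2 for quadrant
    source: tuple[str, ...]         # panel or variant name(s)

    def __post_init__(self) -> None:
        if self.kind not in ("median", "cutoff", "quadrant"):
            raise ValidationError(f"unknown stratification kind {self.kind!r}")
        if any(not np.isfinite(t) for t in self.thresholds):
            raise ValidationError("thresholds must be finite")
        if self.kind == "quadrant" and len(self.thresholds) != 2:
            raise ValidationError("quadrant rule needs exactly two thresholds")


@dataclass
class GroupAssignment:
    labels: pd.Series               # per-sample group label
    rule: StratificationRule

    def __post_init__(self) -> None:
        if self.labels.isna().any():
            raise ValidationError("every sample must receive a label")

    @property
    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def _values_series(values) -> pd.Series:
    if isinstance(values, ScoreVector):
        return values.scores
    if isinstance(values, pd.Series):
        return values
    arr = np.asarray(values, dtype=float)
    return pd.Series(arr, index=[f"s{i}" for i in range(arr.size)])


def median_split(values, source: str = "score") -> GroupAssignment:
    """Split at the sample median; ties at the median go to ``low``."""
    vals = _values_series(values)
    if vals.size < 2:
        raise ValidationError("median split needs at least 2 samples")
    if vals.nunique() == 1:
        raise ValidationError("all values identical: no median split possible")
    threshold = float(vals.median())
    labels = pd.Series(np.where(vals > threshold, "high", "low"), index=vals.index)
    rule = StratificationRule("median", (threshold,), (str(source),))
    return GroupAssignment(labels, rule)


def quadrant_split(th1, th2, sources: tuple[str, str] = ("Th1", "Th2")) -> GroupAssignment:
    """Cross the Th-1 and Th-2 median splits into four quadrants."""
    v1, v2 = _values_series(th1), _values_series(th2)
    if list(v1.index) != list(v2.index):
        raise ValidationError("Th-1 and Th-2 scores must cover the same samples")
    a1 = median_split(v1, sources[0])
    a2 = median_split(v2, sources[1])
    combo = {
        ("high", "high"): "Th1hiTh2hi",
        ("high", "low"): "Th1hiTh2lo",
        ("low", "high"): "Th1loTh2hi",
        ("low", "low"): "Th1loTh2lo",
    }
    labels = pd.Series(
        [combo[(a1.labels[s], a2.labels[s])] for s in v1.index], index=v1.index
    )
    rule = StratificationRule(
        "quadrant", (a1.rule.thresholds[0], a2.rule.thresholds[0]), tuple(sources)
    )
    return GroupAssignment(labels, rule)


def quadrant_hazards(
    assignment: GroupAssignment,
    clinical: ClinicalTable,
    reference: str = "Th1hiTh2lo",
) -> dict[str, SurvivalComparison]:
    """Univariable Cox HR of each quadrant versus the reference quadrant.

    Empty quadrants are omitted with a warning.  The reference-vs-itself
    comparison is not included (its HR is 1 by construction).
    """
    labels = assignment.labels.loc[clinical.sample_ids]
    if (labels == reference).sum() == 0:
        raise ValidationError(f"reference quadrant {reference!r} is empty")
    out: dict[str, SurvivalComparison] = {}
    ref_mask = (labels == reference).to_numpy()
    out[reference] = SurvivalComparison(
        labels=[reference],
        curves={reference: km_estimate(clinical.os_days[ref_mask], clinical.event[ref_mask])},
        logrank=LogrankResult(0.0, 0, 1.0),
        reference=reference,
        hr=1.0,
        ci95=(1.0, 1.0),
        hr_p=1.0,
        notes={"is_reference": True},
    )
    for quad in sorted(set(labels)):
        if quad == reference:
            continue
        mask = labels.isin([reference, quad]).to_numpy()
        if (labels == quad).sum() == 0:  # pragma: no cover
            warnings.warn(f"quadrant {quad!r} empty; HR omitted", UserWarning, stacklevel=2)
            continue
        out[quad] = compare_groups(
            clinical.os_days[mask], clinical.event[mask], labels[mask], reference
        )
    return out


def _admissible_midpoints(vals: np.ndarray, min_group_frac: float) -> np.ndarray:
    distinct = np.unique(vals)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = vals.size
    min_size = min_group_frac * n
    keep = []
    for m in mids:
        lo = np.sum(vals <= m)
        if lo >= min_size and (n - lo) >= min_size:
            keep.append(m)
    return np.asarray(keep)


def optimal_cutoff(
    values,
    times,
    events,
    *,
    min_group_frac: float = 0.1,
    source: str = "expression",
    n_permutations: int = 0,
    seed: int = 0,
) -> tuple[StratificationRule, SurvivalComparison]:
    """Maximally selected survival cutpoint.

    Scans the admissible midpoints, keeps the threshold with the largest
    two-sample log-rank statistic and returns the comparison at that cutoff.
    ``comparison.notes['optimism_biased_p']`` flags the naive p-value; with
    ``n_permutations > 0`` a permutation-adjusted p (re-maximizing on each
    permuted outcome) is added as ``notes['permutation_p']``.
    """
    vals = _values_series(values)
    if not 0.0 < min_group_frac <= 0.5:
        raise ValidationError("min_group_frac must lie in (0, 0.5]")
    if vals.nunique() < 2:
        raise ValidationError("need at least 2 distinct values for a cutoff")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    arr = vals.to_numpy()
    mids = _admissible_midpoints(arr, min_group_frac)
    if mids.size == 0:
        raise ValidationError(
            f"no cutoff leaves both groups with >= {min_group_frac:.0%} of samples"
        )

    def best_stat(perm_t, perm_e):
        best = (-np.inf, np.nan)
        for m in mids:
            g = np.where(arr > m, "high", "low")
            stat = logrank_test(perm_t, perm_e, g).statistic
            if stat > best[0]:
                best = (stat, m)
        return best

    stat, threshold = best_stat(t, e)
    labels = np.where(arr > threshold, "high", "low")
    comparison = compare_groups(t, e, labels, reference="low")
    comparison.notes["optimism_biased_p"] = True
    comparison.notes["n_candidates"] = int(mids.size)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(t.size)
            if best_stat(t[perm], e[perm])[0] >= stat:
                exceed += 1
        comparison.notes["permutation_p"] = (exceed + 1) / (n_permutations + 1)
        comparison.notes["n_permutations"] = n_permutations
    rule = StratificationRule("cutoff", (float(threshold),), (str(source),))
    return rule, comparison


def overlay_by_quadrant(
    data: ExpressionMatrix | dict[str, ScoreVector],
    assignment: GroupAssignment,
) -> pd.DataFrame:
    """Per-quadrant distribution summary for each variant or score.

    Returns a long-format table with quadrant median, type-7 quartiles and
    mean per row, plus the across-quadrant one-way ANOVA F and p.
    """
    if isinstance(data, ExpressionMatrix):
        frame = data.data
    else:
        frame = pd.DataFrame({name: sv.scores for name, sv in data.items()}).T
    missing = set(frame.columns) - set(assignment.labels.index)
    if missing:
        raise ValidationError(f"assignment does not cover samples: {sorted(missing)}")
    labels = assignment.labels.loc[frame.columns]
    rows = []
    for name, row in frame.iterrows():
        groups = [row[labels == q].to_numpy() for q in sorted(set(labels))]
        f, _, _, p = one_way_anova(groups)
        for quad in sorted(set(labels)):
            vals = row[labels == quad]
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])  # type-7 interpolation
            rows.append(
                {
                    "feature": name,
                    "quadrant": quad,
                    "n": int(vals.size),
                    "q1": q1,
                    "median": q2,
                    "q3": q3,
                    "mean": float(vals.mean()),
                    "anova_F": f,
                    "anova_p": p,
                }
            )
    return pd.DataFrame(rows)
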