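"""Prognostic-variable importance and panel-coefficient derivation.

Three complementary views of per-variant prognostic weight are combined:

1. **Permutation importance (VIMP)** from a simplified random survival
   forest.  Trees are grown on bootstrap samples with log-rank splitting:
   each node tries ``mtry`` randomly chosen variants and, per variant, a
   random subset of candidate thresholds (``nsplit``, randomForestSRC
   style; ``nsplit=None`` scans every midpoint exhaustively).  Predictive
   accuracy is expressed in log-rank-statistic units: the out-of-bag
   log-rank statistic of a median split on predicted risk, before minus
   after permuting one variant's values, averaged over trees.
2. **PC1 loadings** of the SD-standardized expression matrix.
3. **Univariable Cox coefficients** on SD-standardized expression.

The combined per-variant index is the rank-average of the three, rescaled to
[0, 1] — a deliberately scale-free combination of heterogeneous inputs; the
method used is recorded in the output so derived panels remain auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import ClinicalTable, Cohort, ExpressionMatrix, ScorePanel
from .exceptions import ValidationError
from .scoring import standardize
from .survival import cox_fit

__all__ = [
    "RSFParams",
    "SurvivalTree",
    "SurvivalForest",
    "rsf_fit",
    "rsf_vimp",
    "pca_loadings",
    "derive_index",
    "importance_table",
    "derive_panel",
]


# ---------------------------------------------------------------------------
# fast two-sample log-rank for split search


def _logrank_stat_2s(t: np.ndarray, e: np.ndarray, g: np.ndarray) -> float:
    """Two-sample log-rank chi-square; ``g`` is a boolean group mask.

    Fully vectorized over the distinct times; returns 0.0 when either group
    is empty or the variance degenerates.
    """
    if g.all() or not g.any() or e.sum() == 0:
        return 0.0
    order = np.argsort(t, kind="stable")
    ts, es, gs = t[order], e[order].astype(float), g[order].astype(float)
    n = ts.size
    uniq, first = np.unique(ts, return_index=True)
    risk = n - first
    suffix_g = np.concatenate([np.cumsum(gs[::-1])[::-1], [0.0]])
    risk1 = suffix_g[first]
    d = np.add.reduceat(es, first)
    d1 = np.add.reduceat(es * gs, first)
    mask = d > 0
    risk, risk1, d, d1 = risk[mask], risk1[mask], d[mask], d1[mask]
    frac = risk1 / risk
    o_minus_e = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1.0 - frac) * (risk - d) / (risk - 1.0)
    var = float(np.nansum(np.where(risk > 1, var_terms, 0.0)))
    if var <= 0:
        return 0.0
    return o_minus_e * o_minus_e / var


def _nelson_aalen_total(t: np.ndarray, e: np.ndarray) -> float:
    """Cumulative hazard at the last observed time (terminal-node risk score)."""
    if e.sum() == 0:
        return 0.0
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order].astype(float)
    uniq, first = np.unique(ts, return_index=True)
    risk = ts.size - first
    d = np.add.reduceat(es, first)
    return float(np.sum(d / risk))


# ---------------------------------------------------------------------------
# forest structures


@dataclass
class RSFParams:
    n_trees: int = 100
    mtry: int | None = None          # default ceil(sqrt(p))
    min_node: int = 15               # no split may leave a child smaller than this
    nsplit: int | None = 10          # random thresholds per variable; None = all midpoints
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_node < 1:
            raise ValidationError("n_trees and min_node must be positive")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be positive")
        if self.nsplit is not None and self.nsplit < 1:
            raise ValidationError("nsplit must be positive or None")


@dataclass
class _Node:
    split_var: int | None = None
    split_val: float = np.nan
    left: "_Node | None" = None
    right: "_Node | None" = None
    risk: float = 0.0                # terminal Nelson-Aalen cumulative hazard
    n: int = 0
    n_events: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None


@dataclass
class SurvivalTree:
    root: _Node
    bootstrap_idx: np.ndarray
    used_variants: set[int]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Terminal-node risk for each row of ``x`` (samples x variants)."""
        out = np.empty(x.shape[0])
        stack = [(self.root, np.arange(x.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf:
                out[idx] = node.risk
                continue
            go_left = x[idx, node.split_var] <= node.split_val
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out


@dataclass
class SurvivalForest:
    trees: list[SurvivalTree]
    variant_ids: list[str]
    params: RSFParams
    n_samples: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Ensemble risk: mean terminal cumulative hazard over trees."""
        return np.mean([tree.predict(x) for tree in self.trees], axis=0)

    def oob_indices(self, tree: SurvivalTree) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        mask[tree.bootstrap_idx] = False
        return np.nonzero(mask)[0]


def _grow_node(x, t, e, idx, params, rng, used: set[int]) -> _Node:
    node = _Node(n=idx.size, n_events=int(e[idx].sum()))
    if idx.size < 2 * params.min_node or e[idx].sum() == 0:
        node.risk = _nelson_aalen_total(t[idx], e[idx])
        return node
    p = x.shape[1]
    mtry = params.mtry or int(np.ceil(np.sqrt(p)))
    candidates = rng.choice(p, size=min(mtry, p), replace=False)
    best = (0.0, None, np.nan)
    for var in candidates:
        vals = x[idx, var]
        distinct = np.unique(vals)
        if distinct.size < 2:
            continue
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        if params.nsplit is not None and mids.size > params.nsplit:
            mids = rng.choice(mids, size=params.nsplit, replace=False)
        for m in mids:
            go_left = vals <= m
            n_left = int(go_left.sum())
            if n_left < params.min_node or idx.size - n_left < params.min_node:
                continue
            stat = _logrank_stat_2s(t[idx], e[idx], go_left)
            if stat > best[0]:
                best = (stat, int(var), float(m))
    if best[1] is None:
        node.risk = _nelson_aalen_total(t[idx], e[idx])
        return node
    _, var, split_val = best
    used.add(var)
    node.split_var = var
    node.split_val = split_val
    go_left = x[idx, var] <= split_val
    node.left = _grow_node(x, t, e, idx[go_left], params, rng, used)
    node.right = _grow_node(x, t, e, idx[~go_left], params, rng, used)
    return node


def rsf_fit(expr: ExpressionMatrix, clinical: ClinicalTable, params: RSFParams | None = None) -> SurvivalForest:
    """Grow a random survival forest on bootstrap samples with log-rank splits.

    Bootstrap samples that contain no event cannot be split on survival and
    are skipped with a warning.
    """
    params = params or RSFParams()
    if expr.sample_ids != clinical.sample_ids:
        raise ValidationError("expression and clinical samples must be aligned")
    x = expr.data.to_numpy().T          # samples x variants
    t = clinical.os_days
    e = clinical.event
    n = x.shape[0]
    rng = np.random.default_rng(params.seed)
    trees: list[SurvivalTree] = []
    skipped = 0
    for _ in range(params.n_trees):
        boot = rng.integers(0, n, size=n)
        if e[boot].sum() == 0:
            skipped += 1
            continue
        used: set[int] = set()
        root = _grow_node(x[boot], t[boot], e[boot], np.arange(n), params, rng, used)
        trees.append(SurvivalTree(root=root, bootstrap_idx=boot, used_variants=used))
    if skipped:
        warnings.warn(
            f"rsf_fit: skipped {skipped} all-censored bootstrap trees", UserWarning, stacklevel=2
        )
    if not trees:
        raise ValidationError("rsf_fit: every bootstrap sample was all-censored")
    return SurvivalForest(trees=trees, variant_ids=expr.variant_ids, params=params, n_samples=n)


def _oob_accuracy(risk: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    """Log-rank statistic of the predicted-risk median split on OOB data."""
    med = np.median(risk)
    high = risk > med
    return _logrank_stat_2s(t, e, high)


def rsf_vimp(
    forest: SurvivalForest,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    seed: int = 0,
) -> pd.Series:
    """Permutation variable importance in log-rank-statistic units.

    Per tree and variant: OOB accuracy (log-rank statistic of the
    predicted-risk median split) minus the same accuracy after permuting that
    variant's OOB values; averaged over trees.  A variant used by no tree has
    VIMP exactly 0.

    One OOB permutation is drawn per tree and reused for every variant, so
    the result is invariant to the ordering of variants in the matrix.
    """
    if expr.variant_ids != forest.variant_ids:
        raise ValidationError("forest was fitted on a different variant set")
    x = expr.data.to_numpy().T
    t = clinical.os_days
    e = clinical.event
    rng = np.random.default_rng(seed)
    p = len(forest.variant_ids)
    totals = np.zeros(p)
    counts = np.zeros(p)
    for tree in forest.trees:
        oob = forest.oob_indices(tree)
        if oob.size < 2 or e[oob].sum() == 0:
            continue
        x_oob = x[oob]
        baseline = _oob_accuracy(tree.predict(x_oob), t[oob], e[oob])
        perm = rng.permutation(oob.size)
        for var in sorted(tree.used_variants):
            x_perm = x_oob.copy()
            x_perm[:, var] = x_perm[perm, var]
            permuted = _oob_accuracy(tree.predict(x_perm), t[oob], e[oob])
            totals[var] += baseline - permuted
        counts += 1  # unused variants contribute an exact 0 for this tree
    vimp = np.divide(totals, counts, out=np.zeros(p), where=counts > 0)
    return pd.Series(vimp, index=forest.variant_ids, name="vimp")


# ---------------------------------------------------------------------------
# PCA / Cox / combined index


def pca_loadings(expr: ExpressionMatrix) -> tuple[pd.Series, np.ndarray]:
    """PC1 loadings and explained-variance fractions of a (standardized) matrix.

    SVD of the sample-centered samples-by-variants matrix; the loading vector
    is sign-fixed so its largest-magnitude entry is positive.  Works in the
    rank-deficient n < p regime; fractions sum to 1 over nonzero components.
    """
    if expr.n_samples < 2 or expr.n_variants < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 variants")
    x = expr.data.to_numpy().T
    xc = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    nonzero = var > var.max() * 1e-12 if var.max() > 0 else var > 0
    fractions = np.zeros_like(var)
    if nonzero.any():
        fractions[nonzero] = var[nonzero] / var[nonzero].sum()
    pc1 = vt[0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=expr.variant_ids, name="pca_loading"), fractions


def _univariable_cox_coefs(
    expr: ExpressionMatrix, clinical: ClinicalTable, variants: list[str]
) -> pd.Series:
    """Cox coefficient per variant on its SD-standardized (z-scored) values."""
    coefs = {}
    t, e = clinical.os_days, clinical.event
    for v in variants:
        vals = expr.data.loc[v].to_numpy()
        sd = vals.std(ddof=1)
        if sd == 0:
            warnings.warn(f"variant {v!r} is constant; Cox coefficient set to nan",
                          UserWarning, stacklevel=3)
            coefs[v] = np.nan
            continue
        z = (vals - vals.mean()) / sd
        try:
            fit = cox_fit(z[:, None], t, e)
            coefs[v] = float(fit.coef[0])
        except Exception as exc:
            warnings.warn(f"Cox fit failed for {v!r} ({exc})", UserWarning, stacklevel=3)
            coefs[v] = np.nan
    return pd.Series(coefs, name="cox_coef")


def derive_index(
    vimp: pd.Series,
    pca_loading: pd.Series,
    cox_coef: pd.Series,
    method: str = "rank_average",
) -> pd.Series:
    """Combine the three importance views into one per-variant index in [0, 1].

    ``rank_average`` (default): average the ascending ranks of ``vimp``,
    ``|pca_loading|`` and ``|cox_coef|`` and rescale so the top-ranked
    variant gets 1 and the bottom-ranked 0; ``vimp_only`` uses the VIMP
    ranking alone.  The chosen method is stored in ``result.attrs``.
    """
    if not (len(vimp) == len(pca_loading) == len(cox_coef)):
        raise ValidationError("importance inputs have mismatched lengths")
    if method == "rank_average":
        parts = [vimp.to_numpy(float), np.abs(pca_loading.to_numpy(float)),
                 np.abs(cox_coef.to_numpy(float))]
        ranks = np.mean([rankdata(p, nan_policy="omit") for p in parts], axis=0)
    elif method == "vimp_only":
        ranks = rankdata(vimp.to_numpy(float), nan_policy="omit")
    else:
        raise ValidationError(f"unknown index method {method!r}")
    n = len(vimp)
    index = (ranks - 1.0) / (n - 1.0) if n > 1 else np.ones(n)
    out = pd.Series(index, index=vimp.index, name="index")
    out.attrs["method"] = method
    return out


def importance_table(
    cohort: Cohort,
    params: RSFParams | None = None,
    *,
    vimp_seed: int = 0,
    index_method: str = "rank_average",
) -> pd.DataFrame:
    """Full per-variant importance table: VIMP, PC1 loading, Cox coef, index."""
    params = params or RSFParams()
    forest = rsf_fit(cohort.expression, cohort.clinical, params)
    vimp = rsf_vimp(forest, cohort.expression, cohort.clinical, seed=vimp_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        std = standardize(cohort.expression)
    loadings, _ = pca_loadings(std)
    coefs = _univariable_cox_coefs(cohort.expression, cohort.clinical, cohort.expression.variant_ids)
    index = derive_index(vimp, loadings, coefs, method=index_method)
    table = pd.DataFrame(
        {"vimp": vimp, "pca_loading": loadings, "cox_coef": coefs, "index": index}
    ).sort_values("index", ascending=False)
    table.attrs["index_method"] = index_method
    table.attrs["rsf_params"] = params
    return table


def derive_panel(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    variants: list[str],
    name: str = "derived",
) -> ScorePanel:
    """Re-derive panel coefficients from a cohort.

    Each coefficient is ``|univariable Cox coefficient on the z-scored
    variant| / SD(variant)`` so the resulting panel applies directly to raw
    FPKM (the per-SD effect is converted back to per-FPKM-unit scale).
    Variants whose Cox fit fails are dropped with a warning.  Derivation
    metadata (method, per-variant SD and signed coefficient) is embedded in
    ``panel.provenance``.
    """
    if not variants:
        raise ValidationError("derive_panel: variant subset is empty")
    missing = [v for v in variants if v not in expr.data.index]
    if missing:
        raise ValidationError(f"variants not in expression matrix: {missing}")
    coefs = _univariable_cox_coefs(expr, clinical, list(variants))
    weights: dict[str, float] = {}
    meta: dict[str, dict] = {}
    for v in variants:
        c = coefs[v]
        if np.isnan(c):
            warnings.warn(f"derive_panel: dropping {v!r} (Cox fit failed)",
                          UserWarning, stacklevel=2)
            continue
        sd = float(expr.data.loc[v].std(ddof=1))
        weights[v] = abs(c) / sd
        meta[v] = {"cox_coef_per_sd": float(c), "sd": sd, "sign": float(np.sign(c))}
    if not weights:
        raise ValidationError("derive_panel: no variant could be fitted")
    return ScorePanel(
        name,
        weights,
        provenance={"method": "abs_cox_per_sd_over_sd", "per_variant": meta,
                    "n": clinical.n_samples, "n_events": int(clinical.event.sum())},
    )
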