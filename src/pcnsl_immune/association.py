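"""Pairwise association and sparse conditional-dependence networks.

Association between transcript-variant expression profiles is measured four
ways: Pearson's r, Spearman's rho, Kendall's tau, and Hoeffding's D — the
last a rank-based U-statistic sensitive to *any* dependence, not just
monotone trends.  The reported Hoeffding statistic is scaled by 30 so that
perfect monotone dependence of continuous data gives exactly 1; its p-value
comes from a seeded permutation test (exact small-n null tables are awkward
and the cohorts here are small).

Network inference solves the graphical lasso: an L1-penalized maximum
likelihood estimate of the precision (inverse covariance) matrix, whose
nonzero off-diagonals are conditional-dependence edges.  Edge weight is the
partial correlation ``-P_ij / sqrt(P_ii P_jj)``; a hub is a node with degree
greater than 2.  When no penalty is given, it is chosen on a small grid by
the extended BIC (gamma = 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso as _sk_glasso

from .data_model import ExpressionMatrix
from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "CorrelationMatrix",
    "PrecisionNetwork",
    "pairwise_association",
    "hoeffding_d",
    "graphical_lasso",
    "extract_network",
    "network_from_expression",
    "select_rho_ebic",
]

METHODS = ("pearson", "spearman", "kendall", "hoeffding")


# ---------------------------------------------------------------------------
# Hoeffding's D


def _hoeffding_scaled(x: np.ndarray, y: np.ndarray) -> float:
    """30*D from midranks and bivariate ranks (ties get 1/2 and 1/4 weights)."""
    n = x.size
    r = stats.rankdata(x)
    s = stats.rankdata(y)
    # Q_i = 1 + #(both strictly less) + tie adjustments
    lx = x[:, None] < x[None, :]
    ly = y[:, None] < y[None, :]
    ex = x[:, None] == x[None, :]
    ey = y[:, None] == y[None, :]
    q = (
        1.0
        + (lx & ly).sum(axis=0)
        + 0.5 * (ex & ly).sum(axis=0)
        + 0.5 * (lx & ey).sum(axis=0)
        + 0.25 * ((ex & ey).sum(axis=0) - 1)  # exclude self-pair
    )
    d1 = np.sum((q - 1) * (q - 2))
    d2 = np.sum((r - 1) * (r - 2) * (s - 1) * (s - 2))
    d3 = np.sum((r - 2) * (s - 2) * (q - 1))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return float(30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom)


def hoeffding_d(x, y, *, n_permutations: int = 1000, seed: int = 0) -> tuple[float, float, float]:
    """Hoeffding's test of independence.

    Returns ``(D, 30*D, permutation p)``.  ``30*D`` equals 1 for perfect
    monotone dependence of continuous data and is near 0 under independence.
    Ties are handled with midranks.  Requires n >= 5 (the U-statistic is
    undefined below that).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 5:
        raise ValidationError("Hoeffding's D requires at least 5 observations")
    scaled = _hoeffding_scaled(x, y)
    p = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = sum(
            _hoeffding_scaled(x, y[rng.permutation(y.size)]) >= scaled
            for _ in range(n_permutations)
        )
        p = (exceed + 1) / (n_permutations + 1)
    return scaled / 30.0, scaled, p


# ---------------------------------------------------------------------------
# pairwise association matrices


@dataclass
class CorrelationMatrix:
    """Per-method symmetric association and p-value matrices."""

    variant_ids: list[str]
    values: dict[str, pd.DataFrame]
    p_values: dict[str, pd.DataFrame]
    undefined_variants: list[str] = field(default_factory=list)

    def matrix(self, method: str) -> pd.DataFrame:
        return self.values[method]


def pairwise_association(
    expr: ExpressionMatrix,
    methods=("pearson", "spearman", "kendall"),
    *,
    n_permutations: int = 200,
    seed: int = 0,
) -> CorrelationMatrix:
    """All-pairs association between variant rows.

    Pearson/Spearman/Kendall use the standard analytic p-values; Hoeffding
    uses a seeded permutation p (``n_permutations`` draws).  Pairs involving
    a zero-variance variant are undefined and reported as NaN (never 0),
    with the offending variants listed in ``undefined_variants``.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown association methods: {sorted(unknown)}")
    if expr.n_samples < 3:
        raise ValidationError("pairwise association needs at least 3 samples")
    data = expr.data
    ids = expr.variant_ids
    sd = data.std(axis=1, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        warnings.warn(
            f"zero-variance variants have undefined associations: {flat}",
            UserWarning,
            stacklevel=2,
        )
    values = {m: pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids) for m in methods}
    pvals = {m: pd.DataFrame(np.nan, index=ids, columns=ids) for m in methods}
    for m in methods:
        for v in flat:
            values[m].loc[v, :] = np.nan
            values[m].loc[:, v] = np.nan
    for i, vi in enumerate(ids):
        for vj in ids[i + 1 :]:
            if vi in flat or vj in flat:
                continue
            x = data.loc[vi].to_numpy()
            y = data.loc[vj].to_numpy()
            for m in methods:
                if m == "pearson":
                    r, p = stats.pearsonr(x, y)
                elif m == "spearman":
                    r, p = stats.spearmanr(x, y)
                elif m == "kendall":
                    r, p = stats.kendalltau(x, y)
                else:
                    _, r, p = hoeffding_d(x, y, n_permutations=n_permutations, seed=seed)
                values[m].loc[vi, vj] = values[m].loc[vj, vi] = r
                pvals[m].loc[vi, vj] = pvals[m].loc[vj, vi] = p
    return CorrelationMatrix(ids, values, pvals, undefined_variants=flat)


# ---------------------------------------------------------------------------
# graphical lasso


@dataclass
class PrecisionNetwork:
    """Sparse precision estimate with its induced conditional-dependence graph."""

    variant_ids: list[str]
    rho: float
    precision: pd.DataFrame
    covariance: pd.DataFrame
    edges: pd.DataFrame              # columns: source, target, partial_r
    degrees: pd.Series
    hubs: list[str]                  # degree > 2
    objective_path: list[float]      # per-iteration penalized NLL (non-increasing)
    n_iter: int


def _check_spd_input(s: np.ndarray) -> None:
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValidationError("covariance must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValidationError("covariance must be symmetric")
    eigs = np.linalg.eigvalsh(s)
    if eigs.min() < -1e-8 * max(eigs.max(), 1.0):
        raise ValidationError("covariance must be positive semidefinite")


def graphical_lasso(
    covariance,
    rho: float,
    *,
    tol: float = 1e-6,
    max_iter: int = 200,
    edge_tol: float = 1e-4,
    mode: str = "lars",
    variant_ids: list[str] | None = None,
) -> PrecisionNetwork:
    """L1-penalized sparse precision estimation.

    Block coordinate-descent maximization of
    ``log det P - tr(S P) - rho * ||P||_1`` (off-diagonal penalty) with a
    LARS inner solver by default (exact for the small panels used here);
    at ``rho = 0`` this reduces to the unpenalized MLE, i.e. the matrix
    inverse.  Non-convergence within ``max_iter`` sweeps raises
    :class:`ConvergenceError` with the final duality gap.
    """
    s = np.asarray(covariance, dtype=float)
    _check_spd_input(s)
    if rho < 0:
        raise ValidationError("penalty rho must be >= 0")
    ids = variant_ids or (
        list(covariance.index) if isinstance(covariance, pd.DataFrame)
        else [f"v{i}" for i in range(s.shape[0])]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cov_est, prec, costs, n_iter = _sk_glasso(
            s, alpha=float(rho), mode=mode, tol=tol, max_iter=max_iter,
            return_costs=True, return_n_iter=True,
        )
    try:
        objective = [float(c[0]) for c in costs]
    except (TypeError, IndexError):  # rho=0 shortcut returns one scalar pair
        objective = [float(costs[0])]
    if rho > 0 and costs:
        gap = float(costs[-1][1])
        if n_iter >= max_iter and gap > tol:
            raise ConvergenceError(
                f"graphical lasso did not converge in {max_iter} sweeps "
                f"(duality gap {gap:.3g} > tol {tol:.3g})"
            )
    prec_df = pd.DataFrame(prec, index=ids, columns=ids)
    edges, degrees, hubs = extract_network(prec_df, edge_tol=edge_tol)
    return PrecisionNetwork(
        variant_ids=list(ids),
        rho=float(rho),
        precision=prec_df,
        covariance=pd.DataFrame(cov_est, index=ids, columns=ids),
        edges=edges,
        degrees=degrees,
        hubs=hubs,
        objective_path=objective,
        n_iter=int(n_iter),
    )


def extract_network(
    precision: pd.DataFrame, *, edge_tol: float = 1e-4
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Edge list, node degrees, and hubs from a precision matrix.

    Edge (i, j) exists iff the partial correlation magnitude
    ``|-P_ij / sqrt(P_ii P_jj)|`` exceeds ``edge_tol``; a hub has degree > 2.
    """
    p = precision.to_numpy()
    ids = list(precision.index)
    d = np.sqrt(np.diag(p))
    partial = -p / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(partial[i, j]) > edge_tol:
                rows.append({"source": ids[i], "target": ids[j], "partial_r": float(partial[i, j])})
    edges = pd.DataFrame(rows, columns=["source", "target", "partial_r"])
    degrees = pd.Series(0, index=ids, dtype=int)
    for _, row in edges.iterrows():
        degrees[row["source"]] += 1
        degrees[row["target"]] += 1
    hubs = degrees.index[degrees > 2].tolist()
    return edges, degrees, hubs


def select_rho_ebic(
    s: np.ndarray, n: int, rho_grid, *, gamma: float = 0.5, tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Pick the penalty minimizing the extended BIC over a grid.

    ``EBIC = -2 * loglik + E log n + 4 E gamma log p`` with ``E`` the edge
    count and ``loglik = (n/2)(log det P - tr(S P))``.
    """
    best = (np.inf, None)
    p_dim = s.shape[0]
    for rho in rho_grid:
        try:
            net = graphical_lasso(s, rho, tol=tol, max_iter=max_iter)
        except (ConvergenceError, FloatingPointError):
            continue
        prec = net.precision.to_numpy()
        sign, logdet = np.linalg.slogdet(prec)
        if sign <= 0:
            continue
        loglik = 0.5 * n * (logdet - np.trace(s @ prec))
        n_edges = len(net.edges)
        ebic = -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p_dim)
        if ebic < best[0]:
            best = (ebic, rho)
    if best[1] is None:
        raise ConvergenceError("EBIC selection: no penalty on the grid converged")
    return float(best[1])


def network_from_expression(
    expr: ExpressionMatrix,
    rho: float | None = None,
    *,
    rho_grid=(0.02, 0.05, 0.1, 0.2, 0.4),
    use_correlation: bool = True,
    edge_tol: float = 1e-4,
) -> PrecisionNetwork:
    """Graphical-lasso network over the variant rows of an expression matrix.

    Zero-variance variants are excluded with a warning.  By default the
    sample *correlation* matrix is analyzed (placing all variants on one
    scale); the penalty is EBIC-selected from ``rho_grid`` when not given,
    and the value used is recorded in the result.
    """
    data = expr.data
    sd = data.std(axis=1, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        warnings.warn(f"excluding zero-variance variants from network: {flat}",
                      UserWarning, stacklevel=2)
        data = data.drop(index=flat)
    if data.shape[0] < 2:
        raise ValidationError("network needs at least 2 non-constant variants")
    x = data.to_numpy()
    s = np.corrcoef(x) if use_correlation else np.cov(x)
    s = (s + s.T) / 2.0
    if rho is None:
        rho = select_rho_ebic(s, n=expr.n_samples, rho_grid=rho_grid)
    return graphical_lasso(s, rho, edge_tol=edge_tol, variant_ids=list(data.index))
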