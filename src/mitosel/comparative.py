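"""Phylogenetic comparative layer: independent contrasts, environment
distance matrices, the Mantel permutation test, and a GLM of omega on
bioclimatic variables with a collinearity screen.

Felsenstein's independent contrasts turn tip traits on a binary tree with
branch lengths into tips-1 statistically independent differences; their
regression must go through the origin.  The Mantel test correlates the
upper triangles of two distance matrices and builds its null by jointly
permuting rows and columns of the second matrix.  The GLM screen is forward
stepwise selection by AIC with a variance-inflation-factor cap, after which
a Gaussian identity-link model is fitted on the retained variables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import spatial, stats

from .codon_usage import RegressionResult
from .io import BIO_COLUMNS
from .tree import Tree

logger = logging.getLogger(__name__)

ZERO_BRANCH_EPSILON = 1e-8


@dataclass
class ContrastSet:
    contrasts: list[tuple[int, float]]  # (internal node postorder index, value)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.contrasts])

    @property
    def node_ids(self) -> list[int]:
        return [i for i, _ in self.contrasts]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix has nonzero diagonal")
        if np.any(m < 0):
            raise ValueError("distance matrix has negative entries")
        self.matrix = m

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.matrix[iu]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int


@dataclass
class GLMResult:
    gene: str
    retained: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    n: int
    aic: float


def pic_contrasts(tree: Tree, trait: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's standardized independent contrasts.

    At each internal node of a binary tree the contrast is
    (x_i - x_j) / sqrt(v_i + v_j) where v are the (possibly extended)
    branch lengths below the node; the node's value is the variance-weighted
    average of its children and its parent branch is extended by
    v_i * v_j / (v_i + v_j).  Zero-length branches are inflated by a small
    epsilon so every contrast is defined.
    """
    if not tree.is_binary():
        raise ValueError("PIC requires a binary tree")
    missing = [t.name for t in tree.tips if t.name not in trait]
    if missing:
        raise ValueError(f"missing trait values for tips: {missing}")
    value: dict[int, float] = {}
    extra: dict[int, float] = {}  # branch-length extension below each node
    contrasts: list[tuple[int, float]] = []
    for node in tree.postorder():
        if node.is_leaf:
            value[node.index] = float(trait[node.name])
            extra[node.index] = 0.0
            continue
        left, right = node.children
        v_i = max(left.length, 0.0) + extra[left.index]
        v_j = max(right.length, 0.0) + extra[right.index]
        if v_i <= 0:
            v_i = ZERO_BRANCH_EPSILON
        if v_j <= 0:
            v_j = ZERO_BRANCH_EPSILON
        contrast = (value[left.index] - value[right.index]) / math.sqrt(v_i + v_j)
        contrasts.append((node.index, contrast))
        value[node.index] = (v_j * value[left.index] + v_i * value[right.index]) / (
            v_i + v_j
        )
        extra[node.index] = v_i * v_j / (v_i + v_j)
    return ContrastSet(contrasts)


def pic_regression(
    x_contrasts: ContrastSet, y_contrasts: ContrastSet
) -> RegressionResult:
    """Regression of y contrasts on x contrasts through the origin.

    Contrasts have an arbitrary sign, so the fit has no intercept (the
    statistical requirement for independent contrasts); slope, R-squared
    and a two-sided t-test p-value for the slope are returned.
    """
    if x_contrasts.node_ids != y_contrasts.node_ids:
        raise ValueError("contrast sets computed on different node sets")
    x = x_contrasts.values
    y = y_contrasts.values
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("zero variance in x contrasts")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    df = n - 1
    se = math.sqrt(ss_res / df / sxx) if ss_res > 0 else 0.0
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = 2 * stats.t.sf(abs(slope / se), df)
    return RegressionResult(slope, 0.0, r2, float(p), n)


def env_distance_matrix(
    env: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distances between species in (z-scored) environment space.

    Zero-variance variables cannot be standardized and are dropped with a
    warning.
    """
    cols = list(columns) if columns is not None else [c for c in BIO_COLUMNS if c in env.columns]
    data = env[cols].astype(float)
    if data.isna().any().any():
        raise ValueError("environment table has missing cells")
    if standardize:
        keep = []
        for c in cols:
            if data[c].std(ddof=1) == 0:
                logger.warning("dropping zero-variance variable %s", c)
            else:
                keep.append(c)
        data = data[keep]
        data = (data - data.mean()) / data.std(ddof=1)
    d = spatial.distance.squareform(spatial.distance.pdist(data.values))
    return DistanceMatrix(list(env.index), d)


def trait_distance_matrix(traits: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance over a species x trait table (e.g. 13-gene omegas)."""
    if traits.isna().any().any():
        raise ValueError("trait table has missing cells")
    d = spatial.distance.squareform(spatial.distance.pdist(traits.values.astype(float)))
    return DistanceMatrix(list(traits.index), d)


def mantel_test(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """One-sided (upper tail) Mantel permutation test.

    r is the Pearson correlation of the upper triangles; the null permutes
    rows and columns of the second matrix jointly;
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    if m1.labels != m2.labels:
        raise ValueError("distance matrices have different labels")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    x = m1.condensed()
    if x.std() == 0:
        raise ValueError("constant off-diagonal entries in first matrix")
    y_full = m2.matrix
    y = m2.condensed()
    if y.std() == 0:
        raise ValueError("constant off-diagonal entries in second matrix")
    n = len(m1.labels)
    iu = np.triu_indices(n, k=1)
    xc = x - x.mean()
    xs = float(np.sqrt(xc @ xc))

    def corr(yv: np.ndarray) -> float:
        yc = yv - yv.mean()
        denom = xs * float(np.sqrt(yc @ yc))
        return float(xc @ yc) / denom

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y_full[np.ix_(perm, perm)][iu]
        if corr(yp) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, seed)


def _vif_ok(X: np.ndarray, cap: float) -> bool:
    """True when every column's variance inflation factor is within cap."""
    if X.shape[1] < 2:
        return True
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        A = sm.add_constant(others)
        fit = sm.OLS(X[:, j], A).fit()
        r2 = min(fit.rsquared, 1 - 1e-12)
        if 1.0 / (1.0 - r2) > cap:
            return False
    return True


def glm_env(
    omega_by_gene: Mapping[str, Mapping[str, float]],
    env: pd.DataFrame,
    vif_cap: float = 10.0,
    columns: Optional[Sequence[str]] = None,
) -> list[GLMResult]:
    """Per-gene Gaussian GLM of omega on screened bioclimatic variables.

    Forward stepwise selection by AIC: at each step the candidate variable
    giving the largest AIC improvement is added, provided the resulting
    design keeps every VIF at or below ``vif_cap``; selection stops when no
    candidate improves AIC.  The final identity-link Gaussian model is
    refitted on the retained variables; genes whose sample size cannot
    support the retained design are refused.
    """
    cols = list(columns) if columns is not None else [c for c in BIO_COLUMNS if c in env.columns]
    results = []
    for gene, omegas in omega_by_gene.items():
        species = [s for s in env.index if s in omegas and not math.isnan(omegas[s])]
        if len(species) < 6:
            raise ValueError(f"gene {gene}: fewer than 6 species with complete data")
        y = np.array([omegas[s] for s in species], dtype=float)
        X_all = env.loc[species, cols].astype(float)
        X_std = (X_all - X_all.mean()) / X_all.std(ddof=1).replace(0, np.nan)
        X_std = X_std.dropna(axis=1)
        retained: list[str] = []
        current_aic = sm.OLS(y, np.ones((len(y), 1))).fit().aic
        improved = True
        while improved:
            improved = False
            best_var, best_aic = None, current_aic
            for var in X_std.columns:
                if var in retained:
                    continue
                trial = retained + [var]
                if len(y) <= len(trial) + 2:
                    continue
                X = X_std[trial].values
                if not _vif_ok(X, vif_cap):
                    continue
                fit = sm.OLS(y, sm.add_constant(X)).fit()
                if fit.aic < best_aic - 1e-9:
                    best_var, best_aic = var, fit.aic
            if best_var is not None:
                retained.append(best_var)
                current_aic = best_aic
                improved = True
        if len(y) <= len(retained) + 1:
            raise ValueError(f"gene {gene}: too few observations for retained design")
        if retained:
            X = sm.add_constant(X_std[retained].values)
            fit = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
            names = ["const"] + retained
            coeffs = dict(zip(names, map(float, fit.params)))
            pvals = dict(zip(names, map(float, fit.pvalues)))
            aic = float(fit.aic)
        else:
            coeffs = {"const": float(y.mean())}
            pvals = {"const": 1.0}
            aic = float(current_aic)
        results.append(GLMResult(gene, retained, coeffs, pvals, len(y), aic))
    return results
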