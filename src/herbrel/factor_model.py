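"""Two-level hierarchical factor reduction of binary property indicators.

First level: the m correlated property indicators are reduced to a small
number of first-order factors by principal-component extraction from the
Pearson (phi) correlation matrix followed by varimax rotation; a variable
joins the factor where its absolute rotated loading is maximal, provided it
clears the loading cut (default |0.4|).  Factor scores are weighted sums of
standardized member variables.  Second level: the same procedure applied to
the first-order factor scores yields core factors, which are named by the
properties whose composite (first x second order) loading clears the naming
cut (default 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoadingMatrix",
    "FactorAssignment",
    "FactorScores",
    "CoreFactor",
    "varimax",
    "first_order_fa",
    "factor_scores",
    "higher_order_fa",
    "composite_loadings",
    "name_core_factor",
    "fold_reduction",
    "HierarchicalFactorModel",
    "hierarchical_reduction",
]


@dataclass
class LoadingMatrix:
    """Rotated loadings (variables x factors) with per-variable uniqueness."""

    loadings: pd.DataFrame
    uniquenesses: pd.Series
    method: str = "pca"
    rotation: str = "varimax"
    dropped: list[str] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def factors(self) -> list[str]:
        return list(self.loadings.columns)


@dataclass
class FactorAssignment:
    """Each variable belongs to at most one factor."""

    factor_of: dict[str, str]
    unassigned: set[str]

    def members(self, factor: str) -> list[str]:
        return [v for v, f in self.factor_of.items() if f == factor]


@dataclass
class FactorScores:
    scores: pd.DataFrame
    weights: dict[str, float]
    means: pd.Series
    sds: pd.Series
    k: dict[str, int]


@dataclass
class CoreFactor:
    id: str
    members: list[str]
    display_name: str = ""


def _varimax_criterion(L: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = L ** 2
    return float((sq ** 2).mean(axis=0).sum() - (sq.mean(axis=0) ** 2).sum())


def _varimax_iterate(
    L: np.ndarray, R0: np.ndarray, tol: float, max_iter: int
) -> np.ndarray:
    p, _ = L.shape
    R = R0
    d = 0.0
    for _ in range(max_iter):
        d_old = d
        B = L @ R
        u, s, vt = np.linalg.svd(L.T @ (B ** 3 - (B * (B ** 2).sum(axis=0)) / p))
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
    return R


def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser), SVD form.

    Run from the identity and from one fixed orthogonal starting rotation
    (perfectly symmetric loading patterns make the identity a saddle point
    of the criterion); the rotation with the larger criterion value wins.
    Deterministic for a given input.
    """
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    starts = [np.eye(k)]
    q, _ = np.linalg.qr(np.random.default_rng(12345).standard_normal((k, k)))
    starts.append(q)
    best, best_val = None, -np.inf
    for R0 in starts:
        R = _varimax_iterate(loadings, R0, tol, max_iter)
        rotated = loadings @ R
        val = _varimax_criterion(rotated)
        if val > best_val + 1e-12:
            best, best_val = rotated, val
    return best


def _orient_and_order(load: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|loading| entry is positive, then
    order columns by explained variance (sum of squared loadings), desc."""
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    order = np.argsort(-(load ** 2).sum(axis=0), kind="stable")
    return load[:, order]


def first_order_fa(
    X: pd.DataFrame | np.ndarray,
    n_factors: int,
    cut: float = 0.4,
    factor_prefix: str = "AC",
) -> tuple[LoadingMatrix, FactorAssignment]:
    """Extract and rotate first-order factors from an observation matrix.

    Pearson correlation matrix -> eigendecomposition -> top ``n_factors``
    components (loadings = eigenvector * sqrt(eigenvalue)) -> varimax.
    Zero-variance columns are removed first and reported in
    ``LoadingMatrix.dropped``.
    """
    if n_factors <= 0:
        raise ValueError("n_factors must be positive")
    X = pd.DataFrame(X)
    X.columns = [str(c) for c in X.columns]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")

    sds = X.std(axis=0, ddof=1)
    dropped = [c for c in X.columns if sds[c] == 0 or math.isnan(sds[c])]
    Xv = X.drop(columns=dropped)
    if Xv.shape[1] == 0:
        raise ValueError("all variables have zero variance")

    corr = np.corrcoef(Xv.to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
    rank = int((eigval > 1e-10).sum())
    if n_factors > rank:
        raise ValueError(f"n_factors={n_factors} exceeds correlation-matrix rank {rank}")

    load = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    load = varimax(load)
    load = _orient_and_order(load)

    names = [f"{factor_prefix}{z+1}" for z in range(n_factors)]
    ldf = pd.DataFrame(load, index=Xv.columns, columns=names)
    uniq = 1.0 - (ldf ** 2).sum(axis=1)
    lm = LoadingMatrix(loadings=ldf, uniquenesses=uniq, dropped=dropped)

    factor_of: dict[str, str] = {}
    unassigned: set[str] = set(dropped)
    for var in ldf.index:
        absrow = ldf.loc[var].abs()
        best = absrow.idxmax()  # ties -> lower factor index (column order)
        if absrow[best] >= cut:
            factor_of[var] = best
        else:
            unassigned.add(var)
    return lm, FactorAssignment(factor_of=factor_of, unassigned=unassigned)


def factor_scores(
    X: pd.DataFrame | np.ndarray, lm: LoadingMatrix, fa: FactorAssignment
) -> FactorScores:
    """Score each observation on each factor.

    score_z = sum over member variables j of w_j * (x_j - mean_j) / SD_j,
    with w_j the member's loading on factor z.
    """
    X = pd.DataFrame(X)
    X.columns = [str(c) for c in X.columns]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    weights: dict[str, float] = {}
    k: dict[str, int] = {f: 0 for f in lm.factors}
    cols = {}
    for factor in lm.factors:
        members = fa.members(factor)
        score = np.zeros(len(X))
        for var in members:
            if sds[var] == 0:
                raise ValueError(f"variable {var!r} has zero standard deviation")
            w = float(lm.loadings.loc[var, factor])
            weights[var] = w
            score = score + w * (X[var].to_numpy(dtype=float) - means[var]) / sds[var]
            k[factor] += 1
        cols[factor] = score
    return FactorScores(
        scores=pd.DataFrame(cols, index=X.index),
        weights=weights,
        means=means,
        sds=sds,
        k=k,
    )


def higher_order_fa(
    first_scores: FactorScores | pd.DataFrame,
    n_core: int,
    cut: float = 0.4,
    core_ids: Optional[Sequence[str]] = None,
) -> tuple[LoadingMatrix, list[CoreFactor]]:
    """Reduce first-order factor scores to core factors (same algorithm)."""
    scores = first_scores.scores if isinstance(first_scores, FactorScores) else first_scores
    if n_core > scores.shape[1]:
        raise ValueError("n_core exceeds the number of first-order factors")
    lm, fa = first_order_fa(scores, n_core, cut=cut, factor_prefix="F")
    if core_ids is None:
        # FA, FB, FC, ... following the column order
        core_ids = ["F" + chr(ord("A") + i) for i in range(n_core)]
    rename = dict(zip(lm.factors, core_ids))
    lm.loadings = lm.loadings.rename(columns=rename)
    fa.factor_of = {v: rename[f] for v, f in fa.factor_of.items()}
    cores = [CoreFactor(id=cid, members=fa.members(cid)) for cid in core_ids]
    return lm, cores


def composite_loadings(
    first_lm: LoadingMatrix,
    first_fa: FactorAssignment,
    second_lm: LoadingMatrix,
    second_fa: FactorAssignment,
) -> pd.DataFrame:
    """Composite loading of each original variable on each core factor:
    (loading of the variable on its first-order factor) x (loading of that
    factor on the core factor it belongs to); zero elsewhere."""
    cores = second_lm.factors
    out = pd.DataFrame(0.0, index=first_lm.variables, columns=cores)
    for var, factor in first_fa.factor_of.items():
        core = second_fa.factor_of.get(factor)
        if core is None:
            continue
        out.loc[var, core] = float(first_lm.loadings.loc[var, factor]) * float(
            second_lm.loadings.loc[factor, core]
        )
    return out


def name_core_factor(
    cf: CoreFactor,
    composites: pd.DataFrame,
    cut: float = 0.5,
    sep: str = "_",
) -> str:
    """Join the labels of properties whose composite loading clears the cut,
    in descending composite order; fall back to ``unnamed_<id>``."""
    col = composites[cf.id]
    passing = col[col >= cut].sort_values(ascending=False)
    if passing.empty:
        return f"unnamed_{cf.id}"
    return sep.join(str(v) for v in passing.index)


def fold_reduction(n_vars: int, n_factors: int, n_parts: int = 9) -> dict:
    """Dimensionality bookkeeping: the fold by which pairwise relation
    testing shrinks when n_vars properties collapse to n_factors factors."""
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    return {
        "fold": n_vars // n_factors,
        "pairs_before": n_parts * n_vars,
        "pairs_after": n_parts * n_factors,
    }


@dataclass
class HierarchicalFactorModel:
    first_lm: LoadingMatrix
    first_fa: FactorAssignment
    first_scores: FactorScores
    second_lm: LoadingMatrix
    second_fa: FactorAssignment
    core_scores: FactorScores
    core_factors: list[CoreFactor]
    composites: pd.DataFrame


def hierarchical_reduction(
    X: pd.DataFrame | np.ndarray,
    n_first: int = 15,
    n_core: int = 3,
    cut: float = 0.4,
    name_cut: float = 0.5,
) -> HierarchicalFactorModel:
    """Run both reduction levels and name the core factors.

    Defaults document the original operating point: 88 property indicators
    reduced to 15 first-order factors and then 3 core factors, loading cut
    |0.4|, naming cut 0.5.
    """
    first_lm, first_fa = first_order_fa(X, n_first, cut=cut)
    fs = factor_scores(X, first_lm, first_fa)
    second_lm, cores = higher_order_fa(fs, n_core, cut=cut)
    # assignment of first-order factors to cores, for scoring & composites
    second_fa = FactorAssignment(
        factor_of={m: cf.id for cf in cores for m in cf.members},
        unassigned=set(first_lm.factors)
        - {m for cf in cores for m in cf.members},
    )
    core_scores = factor_scores(fs.scores, second_lm, second_fa)
    comps = composite_loadings(first_lm, first_fa, second_lm, second_fa)
    for cf in cores:
        cf.display_name = name_core_factor(cf, comps, cut=name_cut)
    return HierarchicalFactorModel(
        first_lm=first_lm,
        first_fa=first_fa,
        first_scores=fs,
        second_lm=second_lm,
        second_fa=second_fa,
        core_scores=core_scores,
        core_factors=cores,
        composites=comps,
    )
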