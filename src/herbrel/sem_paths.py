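"""Structural path regression of core-factor scores on plant-part indicators.

Each core factor F_l is regressed by ordinary least squares on the plant-part
dummy columns (one reference part dropped to avoid the dummy trap, plus an
intercept); every path is reported with its estimator, standard error,
critical ratio (estimator / SE, a t statistic) and two-sided p-value at
n - (number of parts) residual degrees of freedom.  A releveled refit
supplies the reference part's own path so all parts receive estimates.
Significant paths (p below alpha) form the extracted part -> property-group
relations; the estimator sign carries the direction of the association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PathEstimate",
    "RelationSet",
    "fit_paths",
    "extract_relations",
    "interpret_sign",
]

_DEGENERATE_MSE = 1e-12


@dataclass(frozen=True)
class PathEstimate:
    source: str
    target: str
    estimator: float
    se: float
    cr: float
    p: float
    residual_label: str = ""
    estimable: bool = True
    degenerate: bool = False


@dataclass
class RelationSet:
    relations: list[tuple[str, str, str]]  # (source, target, sign)
    alpha: float
    estimates: list[PathEstimate] = field(default_factory=list)


def _ols_block(
    y: np.ndarray,
    pp: np.ndarray,
    labels: Sequence[str],
    ref: int,
    target: str,
) -> dict[str, PathEstimate]:
    """One OLS fit with the ``ref`` part dropped; paths for present parts."""
    keep = [i for i in range(pp.shape[1]) if i != ref]
    X = sm.add_constant(pp[:, keep].astype(float), has_constant="add")
    res = sm.OLS(y, X).fit()
    degenerate = res.mse_resid < _DEGENERATE_MSE
    out = {}
    for pos, i in enumerate(keep, start=1):
        est = float(res.params[pos])
        se = float(res.bse[pos])
        out[labels[i]] = PathEstimate(
            source=labels[i],
            target=target,
            estimator=est,
            se=se,
            cr=float(res.tvalues[pos]) if not degenerate else float("nan"),
            p=float(res.pvalues[pos]) if not degenerate else float("nan"),
            residual_label=f"delta[{target}]",
            degenerate=degenerate,
        )
    return out


def fit_paths(
    core_scores: pd.DataFrame | np.ndarray,
    pp: pd.DataFrame | np.ndarray,
    part_labels: Optional[Sequence[str]] = None,
    reference: Optional[str] = None,
) -> list[PathEstimate]:
    """Fit every part -> core-factor path by dummy-coded OLS.

    ``core_scores`` is observations x L (one column per core factor);
    ``pp`` is the observations x n_parts one-hot part matrix.  The reference
    part (default: the last) is dropped from the main fit and recovered from
    a releveled refit against the first part.  Parts with no observations are
    flagged not estimable.
    """
    scores = pd.DataFrame(core_scores)
    scores.columns = [str(c) for c in scores.columns]
    pp = pd.DataFrame(pp)
    if part_labels is None:
        part_labels = [str(c) for c in pp.columns]
    P = pp.to_numpy(dtype=float)
    n, n_parts = P.shape
    if n < n_parts + 2:
        raise ValueError(f"need at least {n_parts + 2} observations, got {n}")
    if not np.all(P.sum(axis=1) == 1):
        raise ValueError("pp columns must be one-hot per observation")

    counts = P.sum(axis=0)
    ref = n_parts - 1 if reference is None else list(part_labels).index(reference)
    alt_ref = 0 if ref != 0 else 1

    out: list[PathEstimate] = []
    for target in scores.columns:
        y = scores[target].to_numpy(dtype=float)
        main = _ols_block(y, P, part_labels, ref, target)
        relevel = _ols_block(y, P, part_labels, alt_ref, target)
        for i, label in enumerate(part_labels):
            if counts[i] == 0:
                out.append(
                    PathEstimate(
                        source=label,
                        target=target,
                        estimator=float("nan"),
                        se=float("nan"),
                        cr=float("nan"),
                        p=float("nan"),
                        residual_label=f"delta[{target}]",
                        estimable=False,
                    )
                )
            elif label in main:
                out.append(main[label])
            else:
                out.append(relevel[label])
    return out


def extract_relations(
    estimates: Sequence[PathEstimate], alpha: float = 0.05
) -> RelationSet:
    """Keep paths with p < alpha; the estimator sign labels the relation."""
    kept = []
    for e in estimates:
        if e.estimable and not e.degenerate and not np.isnan(e.p) and e.p < alpha:
            sign = "positive" if e.estimator >= 0 else "negative"
            kept.append((e.source, e.target, sign))
    return RelationSet(relations=kept, alpha=alpha, estimates=list(estimates))


def interpret_sign(pe: PathEstimate) -> str:
    """Narrative reading of a path estimate's sign."""
    if pe.estimator > 0:
        return (
            f"increasing use of {pe.source} increases the improved "
            f"symptom(s) of {pe.target}"
        )
    if pe.estimator < 0:
        return (
            f"increasing use of {pe.source} decreases the degree of "
            f"symptom(s) of {pe.target}"
        )
    return f"use of {pe.source} shows no association with {pe.target}"


def estimates_frame(estimates: Sequence[PathEstimate], alpha: float = 0.05) -> pd.DataFrame:
    """Tabular view: source, target, estimator, se, cr, p, significant, sign."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "source": e.source,
                "target": e.target,
                "estimator": e.estimator,
                "se": e.se,
                "cr": e.cr,
                "p": e.p,
                "significant": bool(e.estimable and not e.degenerate and not np.isnan(e.p) and e.p < alpha),
                "sign": "positive" if e.estimator >= 0 else "negative",
            }
        )
    return pd.DataFrame(rows)
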