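"""Empirical accuracy estimation in a reference population.

Provides leave-one-out (LOO) cross-validation EBV and their accuracy, the
selection-index addition of own-phenotype information to the LOO accuracy,
and the LR part-whole method that infers GEBV accuracy from the correlation
between pedigree and genomic EBV.

The LOO EBV are computed exactly (identical to n refits, each re-estimating
the overall mean) from a single factorization of V = K + lambda*I on the
phenotyped set.  Writing W = V^-1, u = W y, v = W 1, removing record i gives

    K[i, -i] (V[-i, -i])^-1 y[-i]  =  y_i - u_i / w_ii,
    K[i, -i] (V[-i, -i])^-1 1      =  1  - v_i / w_ii,

and the GLS mean of the reduced data follows from rank-one downdates of
1'W1 and 1'Wy, so each LOO EBV costs O(1) after the O(n^3) factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np
import pandas as pd

from .blup_engine import solve_blup
from .relationships import RelationshipMatrix

__all__ = [
    "LooIndex",
    "loo_ebv",
    "loo_accuracy",
    "add_own_phenotype",
    "lr_accuracy",
]


@dataclass(frozen=True)
class LooIndex:
    """LOO accuracy with the index weights that add own phenotype back in."""

    r_loo: float
    h2: float
    b_loo: float
    b_y: float


def loo_ebv(
    K: RelationshipMatrix,
    phen: pd.DataFrame,
    h2: float,
    kind: str = "LOO_G",
    method: Literal["downdate", "refit"] = "downdate",
) -> pd.DataFrame:
    """Leave-one-out EBV: each individual's EBV with its own record removed.

    ``method='downdate'`` uses the closed-form identity above (O(n^3) total);
    ``method='refit'`` runs n independent BLUP solves and exists as the
    brute-force oracle.  Both re-estimate the overall mean without record i.
    """
    n = len(phen)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 phenotyped individuals")
    if not (0.0 < h2 < 1.0):
        raise ValueError(f"h2 must be strictly inside (0, 1), got {h2}")
    ids = phen["id"].to_numpy()

    if method == "refit":
        out = np.empty(n)
        for i in range(n):
            reduced = phen.drop(phen.index[i])
            fit = solve_blup(K, reduced, h2, kind=kind, evaluate_ids=[ids[i]])
            out[i] = fit["ebv"].iloc[0]
        return pd.DataFrame({"id": ids, "ebv": out, "kind": kind})
    if method != "downdate":
        raise ValueError(f"unknown method {method!r}")

    pos = {int(i): j for j, i in enumerate(K.ids)}
    obs = np.array([pos[int(i)] for i in ids])
    y = phen["value"].to_numpy(dtype=float)
    lam = (1.0 - h2) / h2
    V = K.values[np.ix_(obs, obs)] + lam * np.eye(n)
    W = np.linalg.inv(V)
    u = W @ y
    v = W.sum(axis=1)  # W @ 1
    w = np.diag(W).copy()
    S_11 = float(v.sum())  # 1' W 1
    S_1y = float(u @ np.ones(n))  # 1' W y

    # GLS mean of the n-1 remaining records, by rank-one downdate of W
    s1 = (S_11 - 2.0 * v + w) - (v - w) ** 2 / w
    s2 = (S_1y - v * y - u + w * y) - (v - w) * (u - w * y) / w
    mu_loo = s2 / s1
    ebv = (y - u / w) - mu_loo * (1.0 - v / w)
    return pd.DataFrame({"id": ids, "ebv": ebv, "kind": kind})


def loo_accuracy(
    loo: pd.DataFrame,
    phen_adjusted: pd.DataFrame,
    h2: float,
    groups: Optional[np.ndarray] = None,
    policy: Literal["cap", "strict"] = "cap",
):
    """Accuracy of EBV from LOO cross-validation.

    ``r = cor(g_loo, y_adjusted) / sqrt(h2)`` where phenotypes are adjusted
    for fixed effects (in the simulated designs here, the overall mean; the
    correlation itself is shift-invariant).  With ``groups`` given, a table
    of per-group accuracies plus the pooled estimate is returned; the pooled
    value is what downstream ``Me`` estimation consumes.  Estimates above 1
    are capped with a warning (``policy='cap'``) or raise
    (``policy='strict'``).
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    merged = loo.merge(phen_adjusted, on="id", suffixes=("", "_y"))
    g = merged["ebv"].to_numpy(dtype=float)
    y = merged["value"].to_numpy(dtype=float)

    def one(gv: np.ndarray, yv: np.ndarray) -> float:
        if np.std(gv) == 0.0 or np.std(yv) == 0.0:
            raise ValueError("zero variance; LOO accuracy undefined")
        r = float(np.corrcoef(gv, yv)[0, 1]) / np.sqrt(h2)
        if r > 1.0:
            if policy == "strict":
                raise ValueError(f"estimated accuracy {r:.4g} exceeds 1")
            warnings.warn(
                f"estimated accuracy {r:.4g} exceeds 1; capping", stacklevel=3
            )
            r = 1.0
        return r

    if groups is None:
        return one(g, y)
    groups = np.asarray(groups)
    rows = [{"group": "pooled", "r": one(g, y)}]
    for grp in np.unique(groups):
        mask = groups == grp
        rows.append({"group": grp, "r": one(g[mask], y[mask])})
    return pd.DataFrame(rows)


def add_own_phenotype(r_loo: float, h2: float) -> Tuple[float, LooIndex]:
    """Accuracy after indexing the LOO EBV with the individual's own phenotype.

    ``r^2 = (r_loo^2 + h2 - 2 h2 r_loo^2) / (1 - h2 r_loo^2)`` with index
    weights ``b_loo = (1 - h2) / (1 - h2 r_loo^2)`` and
    ``b_y = h2 (1 - r_loo^2) / (1 - h2 r_loo^2)``.
    """
    if not (0.0 <= r_loo <= 1.0):
        raise ValueError(f"r_loo must be in [0, 1], got {r_loo}")
    if not (0.0 < h2 < 1.0):
        raise ValueError(f"h2 must be strictly inside (0, 1), got {h2}")
    r2l = r_loo**2
    denom = 1.0 - h2 * r2l
    r2 = (r2l + h2 - 2.0 * h2 * r2l) / denom
    weights = LooIndex(
        r_loo=r_loo,
        h2=h2,
        b_loo=(1.0 - h2) / denom,
        b_y=h2 * (1.0 - r2l) / denom,
    )
    return float(np.sqrt(r2)), weights


def lr_accuracy(r_A_hat: float, cor_AG: float) -> float:
    """GEBV accuracy by the LR part-whole method.

    The correlation between pedigree (partial) and genomic (whole) EBV equals
    the ratio of their accuracies, so ``r_G = r_A / cor(g_A, g_G)``.
    """
    if cor_AG <= 0.0 or cor_AG > 1.0:
        raise ValueError(f"cor_AG must be in (0, 1], got {cor_AG}")
    if not (0.0 < r_A_hat <= 1.0):
        raise ValueError(f"r_A_hat must be in (0, 1], got {r_A_hat}")
    r = r_A_hat / cor_AG
    if r > 1.0:
        raise ValueError(
            f"implied GEBV accuracy {r:.4g} exceeds 1: r_A_hat and cor_AG are "
            "inconsistent"
        )
    return r
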