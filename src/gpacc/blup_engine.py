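"""Single-trait animal-model BLUP with an arbitrary relationship matrix.

Solves the mixed-model equations with the overall mean as the only fixed
effect.  Rather than inverting the relationship matrix, the equivalent
variance-component form is used: with phenotyped set ``o``,

    V = K[o, o] + lambda * I,      lambda = (1 - h2) / h2,
    mu_hat = (1' V^-1 y) / (1' V^-1 1)          (generalized least squares),
    g_hat  = K[:, o] V^-1 (y - mu_hat),

which is algebraically identical to the MME solution and extends EBV to
unphenotyped individuals through their relationships.  Population accuracy
is the Pearson correlation between EBV and true breeding values, optionally
after centering within generation to remove genetic trend.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .relationships import RelationshipMatrix

__all__ = ["solve_blup", "population_accuracy", "read_ebv_table", "write_ebv_table"]


def solve_blup(
    K: RelationshipMatrix,
    phen: pd.DataFrame,
    h2: float,
    kind: str = "G",
    evaluate_ids: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """BLUP breeding values for all (or selected) individuals in ``K``.

    Parameters
    ----------
    K:
        Relationship matrix (pedigree ``A`` or genomic ``G``) covering all
        phenotyped and evaluated individuals.
    phen:
        Phenotype table with columns ``id`` and ``value`` (one record per
        individual).
    h2:
        Heritability used for evaluation, strictly inside (0, 1).
    kind:
        Label stored in the output table (e.g. ``"A"`` or ``"G"``).
    evaluate_ids:
        Ids to return EBV for; defaults to every id in ``K``.

    Returns
    -------
    DataFrame with columns (id, ebv, kind).
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError(f"h2 must be strictly inside (0, 1), got {h2}")
    if phen["id"].duplicated().any():
        raise ValueError("one phenotype record per individual is required")
    ids = K.ids
    pos = {int(i): j for j, i in enumerate(ids)}
    try:
        obs = np.array([pos[int(i)] for i in phen["id"]])
    except KeyError as exc:
        raise ValueError(f"phenotyped id {exc} absent from relationship matrix")
    y = phen["value"].to_numpy(dtype=float)
    lam = (1.0 - h2) / h2

    V = K.values[np.ix_(obs, obs)] + lam * np.eye(len(obs))
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "relationship matrix is not positive (semi)definite on the "
            "phenotyped set"
        ) from exc
    ones = np.ones(len(obs))
    Vi_y = cho_solve(cf, y)
    Vi_1 = cho_solve(cf, ones)
    mu = float(ones @ Vi_y) / float(ones @ Vi_1)
    alpha = cho_solve(cf, y - mu)

    if evaluate_ids is None:
        eval_idx = np.arange(len(ids))
        eval_ids = ids
    else:
        eval_idx = np.array([pos[int(i)] for i in evaluate_ids])
        eval_ids = np.asarray(evaluate_ids)
    ebv = K.values[np.ix_(eval_idx, obs)] @ alpha
    return pd.DataFrame({"id": eval_ids, "ebv": ebv, "kind": kind})


def population_accuracy(
    ebv: np.ndarray,
    tbv: np.ndarray,
    generation: Optional[np.ndarray] = None,
    center_by: Optional[str] = None,
) -> float:
    """Correlation between EBV and true breeding values across a population.

    With ``center_by='generation'`` both vectors are centered within
    generation before pooling, so that genetic trend does not inflate the
    correlation (relevant under selection).
    """
    ebv = np.asarray(ebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if ebv.shape != tbv.shape:
        raise ValueError("ebv and tbv must have matching shapes")
    if center_by == "generation":
        if generation is None:
            raise ValueError("center_by='generation' requires a generation vector")
        generation = np.asarray(generation)
        e = ebv.astype(float).copy()
        t = tbv.astype(float).copy()
        for g in np.unique(generation):
            mask = generation == g
            if mask.sum() < 3:
                raise ValueError(
                    f"generation {g} has fewer than 3 individuals; cannot center"
                )
            e[mask] -= e[mask].mean()
            t[mask] -= t[mask].mean()
        ebv, tbv = e, t
    elif center_by not in (None, "none"):
        raise ValueError(f"unknown center_by {center_by!r}")
    if np.std(ebv) == 0.0 or np.std(tbv) == 0.0:
        raise ValueError("zero variance in EBV or TBV; correlation undefined")
    return float(np.corrcoef(ebv, tbv)[0, 1])


def read_ebv_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ebv_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
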