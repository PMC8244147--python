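"""Replicated experiment drivers and the real-data decline regression.

Ties the simulator, BLUP engine and accuracy algebra together into the two
validation designs — single-generation reference populations at increasing
distance from a fixed target generation, and a reference population that
accumulates generations while always targeting the next one — plus the
log-accuracy decline regression used on real multi-generation
cross-validation results, and a helper that calibrates the segment-size
inflation factor gamma against observed target accuracies.

Replicate averaging follows the validation convention: empirical accuracies
are averaged over replicates first and the averaged accuracies are then
transformed into Me estimates and predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import accuracy_core as ac
from .blup_engine import population_accuracy, solve_blup
from .relationships import Pedigree, build_A, me_from_relationship_variance
from .simulator import SimConfig, SimDataset, simulate_breeding, simulate_historical

__all__ = [
    "ExperimentResult",
    "DeclineRegressionResult",
    "run_single_gen_experiment",
    "run_accumulating_experiment",
    "decline_regression",
    "decline_from_coefficients",
    "calibrate_gamma",
]


@dataclass
class ExperimentResult:
    """Averaged accuracies, Me estimates and target predictions of one design."""

    accuracies: pd.DataFrame  # config, scope, kind, r (replicate-averaged)
    me: pd.DataFrame  # config, method, Me
    predictions: pd.DataFrame  # config, combine, p_rt, r_Dt, r_At, r_Gt_pred, r_Gt_emp
    n_reps: int
    config: SimConfig
    replicates: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class DeclineRegressionResult:
    """Log-linear decline of DEBV accuracy across validation generations.

    ``slope``/``intercept`` are the OLS coefficients of ln(r_D) on the
    generation gap.  ``me_from_slope`` solves the per-generation squared
    retention factor ``(1 - gamma*k*L/Me)^2 = exp(slope)`` (the exponent of
    the erosion model grows by 2 per generation); ``me_from_intercept`` runs
    the Index-route Me solver on ``r_Dr = exp(intercept)``.
    """

    slope: float
    intercept: float
    me_from_slope: float
    me_from_intercept: float
    r_Dr_hat: float
    q2: float
    per_gen_factor_D: float
    slope_A: Optional[float] = None
    per_gen_factor_A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.me_from_slope <= 0 or self.me_from_intercept <= 0:
            raise ValueError("Me estimates must be positive")
        if not (0.0 < self.r_Dr_hat < 1.0):
            raise ValueError("r_Dr_hat must be in (0, 1)")


# ---------------------------------------------------------------------------
# per-replicate genetic evaluation
# ---------------------------------------------------------------------------


def _evaluate(
    data: SimDataset,
    ref_gens: Sequence[int],
    target_gen: int,
) -> dict:
    """Empirical accuracies of PEBV and GEBV for one replicate.

    Reference individuals are evaluated with their own phenotype in the data
    (within-sample accuracy, centered within generation); target individuals
    are unphenotyped and receive EBV through relationships only.
    """
    from .relationships import build_G  # local import to keep module load light

    ped = data.pedigree
    gens = list(ref_gens) + [target_gen]
    ids = data.ids_of(gens)
    rows = data.rows_of(ids)
    generation = ped["generation"].to_numpy()[rows]
    is_ref = np.isin(generation, list(ref_gens))
    ref_ids = ids[is_ref]

    # the numerator relationship needs the full ancestry, not just the
    # evaluated generations; individuals are in birth order so everything up
    # to the latest needed generation is a closed pedigree
    ped_full = Pedigree(
        ped.loc[ped["generation"] <= max(gens), ["id", "sire", "dam", "generation"]]
        .reset_index(drop=True)
    )
    A = build_A(ped_full).subset(ids)
    G = build_G(
        data.markers[rows].astype(float), ids, method=data.config.g_method
    )
    phen = data.phenotype_table(ref_ids)[["id", "value"]]
    h2 = data.config.h2
    out = {}
    for kind, K in (("A", A), ("G", G)):
        fit = solve_blup(K, phen, h2, kind=kind, evaluate_ids=ids)
        ebv = fit["ebv"].to_numpy()
        tbv = data.tbv[rows]
        out[f"r_{kind}_ref"] = population_accuracy(
            ebv[is_ref], tbv[is_ref], generation[is_ref], center_by="generation"
        )
        out[f"r_{kind}_target"] = population_accuracy(ebv[~is_ref], tbv[~is_ref])
    out["me_var_GA"] = me_from_relationship_variance(
        G.subset(ref_ids), A.subset(ref_ids)
    )
    out["n_ref"] = len(ref_ids)
    return out


def _me_and_predictions(
    avg: pd.Series,
    cfg: SimConfig,
    gamma: float,
    gap: int,
    M: int,
) -> tuple[list[dict], list[dict]]:
    """Turn replicate-averaged accuracies into Me estimates and predictions."""
    h2 = cfg.h2
    N = avg["n_ref"]
    dist = ac.DistanceToReference(gap, gap)
    me_rows, pred_rows = [], []

    me_f = ac.me_fisher(avg["r_G_ref"], avg["r_A_ref"], h2, N, M)
    r_D2_index = ac.index_extract_rD2(avg["r_G_ref"] ** 2, avg["r_A_ref"] ** 2)
    me_i, q2_i = ac.me_index(math.sqrt(r_D2_index), h2, N, M)
    me_rows.append({"method": "fisher", "Me": me_f})
    me_rows.append({"method": "index", "Me": me_i})
    me_rows.append({"method": "var_GA", "Me": avg["me_var_GA"]})

    for combine, me in (("fisher", me_f), ("index", me_i)):
        ctx = ac.PredictionContext(
            h2=h2, N=N, M=M, Me=me, k=cfg.genome.k, L=cfg.genome.L, gamma=gamma
        )
        # reference-scale r_D implied by this route's Me
        ref = ac.predict_reference_accuracy(avg["r_A_ref"], ctx, combine=combine)
        pred = ac.predict_target_accuracy(
            ref.r_D, avg["r_A_target"], ctx, dist, combine=combine
        )
        pred_rows.append(
            {
                "combine": combine,
                "Me": me,
                "p_rt": ac.p_rt(me, cfg.genome.k, cfg.genome.L, gamma, dist),
                "r_Dr": ref.r_D,
                "r_Gr_pred": ref.r_G,
                "r_Gr_emp": avg["r_G_ref"],
                "r_Dt": pred.r_D,
                "r_At": avg["r_A_target"],
                "r_Gt_pred": pred.r_G,
                "r_Gt_emp": avg["r_G_target"],
            }
        )
    return me_rows, pred_rows


def _simulate_replicates(
    cfg: SimConfig, n_reps: int, base_seed: int
) -> List[SimDataset]:
    datasets = []
    for rep in range(n_reps):
        rep_cfg = _with_seed(cfg, base_seed + rep)
        pool = simulate_historical(
            cfg.genome,
            ne=cfg.hist_ne,
            n_generations=cfg.n_hist_generations,
            seed=base_seed + rep,
        )
        datasets.append(simulate_breeding(rep_cfg, pool))
    return datasets


def _with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    import dataclasses

    return dataclasses.replace(cfg, seed=seed)


def run_single_gen_experiment(
    cfg: SimConfig,
    reference_gens: Sequence[int] = (5, 6, 7, 8, 9),
    target_gen: int = 10,
    n_reps: int = 50,
    gamma: float = 2.0,
    base_seed: int = 0,
    datasets: Optional[List[SimDataset]] = None,
) -> ExperimentResult:
    """Single-generation reference populations at varying distance to a target.

    Each listed generation serves as the reference on its own while
    ``target_gen`` is predicted, so the generation gap (and with it the
    erosion factor ``p_rt``) varies from wide to narrow.
    """
    if datasets is None:
        datasets = _simulate_replicates(cfg, n_reps, base_seed)
    M = datasets[0].markers.shape[1]
    rep_rows = []
    for rep, data in enumerate(datasets):
        for ref_gen in reference_gens:
            res = _evaluate(data, [ref_gen], target_gen)
            res.update({"rep": rep, "ref_gen": ref_gen})
            rep_rows.append(res)
    reps = pd.DataFrame(rep_rows)
    acc_rows, me_rows, pred_rows = [], [], []
    for ref_gen, group in reps.groupby("ref_gen"):
        avg = group.mean(numeric_only=True)
        gap = target_gen - ref_gen
        me_part, pred_part = _me_and_predictions(avg, cfg, gamma, gap, M)
        for row in me_part:
            me_rows.append({"ref_gen": ref_gen, **row})
        for row in pred_part:
            pred_rows.append({"ref_gen": ref_gen, "gap": gap, **row})
        for kind in ("A", "G"):
            for scope in ("ref", "target"):
                acc_rows.append(
                    {
                        "ref_gen": ref_gen,
                        "scope": scope,
                        "kind": kind,
                        "r": avg[f"r_{kind}_{scope}"],
                    }
                )
    return ExperimentResult(
        accuracies=pd.DataFrame(acc_rows),
        me=pd.DataFrame(me_rows),
        predictions=pd.DataFrame(pred_rows),
        n_reps=len(datasets),
        config=cfg,
        replicates=reps,
    )


def run_accumulating_experiment(
    cfg: SimConfig,
    n_reps: int = 50,
    gamma: float = 2.0,
    base_seed: int = 0,
    datasets: Optional[List[SimDataset]] = None,
) -> ExperimentResult:
    """Accumulating reference population always targeting the next generation.

    Starting from generation 0 as reference for target generation 1, each
    step adds the previous target to the reference, mimicking an ongoing
    breeding program; the generation distance stays (1, 1).
    """
    if datasets is None:
        datasets = _simulate_replicates(cfg, n_reps, base_seed)
    M = datasets[0].markers.shape[1]
    rep_rows = []
    for rep, data in enumerate(datasets):
        for target_gen in range(1, cfg.n_generations + 1):
            res = _evaluate(data, list(range(target_gen)), target_gen)
            res.update({"rep": rep, "target_gen": target_gen})
            rep_rows.append(res)
    reps = pd.DataFrame(rep_rows)
    acc_rows, me_rows, pred_rows = [], [], []
    for target_gen, group in reps.groupby("target_gen"):
        avg = group.mean(numeric_only=True)
        me_part, pred_part = _me_and_predictions(avg, cfg, gamma, 1, M)
        for row in me_part:
            me_rows.append({"target_gen": target_gen, **row})
        for row in pred_part:
            pred_rows.append({"target_gen": target_gen, "gap": 1, **row})
        for kind in ("A", "G"):
            for scope in ("ref", "target"):
                acc_rows.append(
                    {
                        "target_gen": target_gen,
                        "scope": scope,
                        "kind": kind,
                        "r": avg[f"r_{kind}_{scope}"],
                    }
                )
    return ExperimentResult(
        accuracies=pd.DataFrame(acc_rows),
        me=pd.DataFrame(me_rows),
        predictions=pd.DataFrame(pred_rows),
        n_reps=len(datasets),
        config=cfg,
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# decline regression (real-data workflow)
# ---------------------------------------------------------------------------


def decline_regression(
    accuracy_table: pd.DataFrame,
    h2: float,
    N: float,
    M: float,
    kL: float,
    gamma: float = 2.0,
    policy: str = "clamp",
) -> DeclineRegressionResult:
    """Fit the log-linear decline of DEBV accuracy over validation generations.

    ``accuracy_table`` needs columns ``gap`` (generations between validation
    and reference), ``r_G`` and ``r_A``.  Per gap, ``r_D`` is extracted with
    the Index relation; gaps where genomic accuracy falls at or below
    pedigree accuracy are dropped with a warning.  Ordinary least squares of
    ln(r_D) on gap yields the slope and intercept from which the two ``Me``
    estimates are derived.
    """
    required = {"gap", "r_G", "r_A"}
    if not required <= set(accuracy_table.columns):
        raise ValueError(f"accuracy table needs columns {sorted(required)}")
    gaps, ln_rd, ln_ra = [], [], []
    for rec in accuracy_table.itertuples(index=False):
        r_D2 = ac.index_extract_rD2(rec.r_G**2, rec.r_A**2, policy=policy)
        if r_D2 <= 0.0:
            warnings.warn(
                f"gap {rec.gap}: r_G <= r_A leaves no genomic signal; dropped",
                stacklevel=2,
            )
            continue
        gaps.append(rec.gap)
        ln_rd.append(0.5 * math.log(r_D2))
        ln_ra.append(math.log(rec.r_A))
    if len(gaps) < 2:
        raise ValueError("fewer than 2 usable generation gaps")
    slope, intercept = np.polyfit(gaps, ln_rd, 1)
    slope_A = float(np.polyfit(gaps, ln_ra, 1)[0])
    return decline_from_coefficients(
        float(slope), float(intercept), h2, N, M, kL, gamma, slope_A=slope_A
    )


def decline_from_coefficients(
    slope: float,
    intercept: float,
    h2: float,
    N: float,
    M: float,
    kL: float,
    gamma: float = 2.0,
    slope_A: Optional[float] = None,
) -> DeclineRegressionResult:
    """Me estimates from already-fitted decline-regression coefficients.

    The per-generation retention factor of DEBV accuracy is
    ``exp(slope) = (1 - gamma*kL/Me)^2`` (the erosion exponent grows by 2
    each generation), so ``Me = gamma*kL / (1 - exp(slope/2))``.  The
    intercept extrapolates the DEBV accuracy to gap 0, i.e. to the reference
    population itself, and feeds the Index-route ``Me`` solver.
    """
    if slope >= 0.0:
        raise ValueError("decline slope must be negative")
    me_slope = gamma * kL / (1.0 - math.exp(slope / 2.0))
    r_Dr = math.exp(intercept)
    me_icpt, q2 = ac.me_index(r_Dr, h2, N, M)
    return DeclineRegressionResult(
        slope=slope,
        intercept=intercept,
        me_from_slope=me_slope,
        me_from_intercept=me_icpt,
        r_Dr_hat=r_Dr,
        q2=q2,
        per_gen_factor_D=math.exp(slope),
        slope_A=slope_A,
        per_gen_factor_A=math.exp(slope_A) if slope_A is not None else None,
    )


# ---------------------------------------------------------------------------
# gamma calibration
# ---------------------------------------------------------------------------


def calibrate_gamma(
    observed: pd.DataFrame,
    r_D_ref: float,
    r_A_target: pd.Series | np.ndarray | None,
    ctx_base: ac.PredictionContext,
    combine: str = "index",
) -> float:
    """Segment-size inflation factor that best explains observed target accuracies.

    ``observed`` needs columns ``gap`` and ``r_G`` (observed target GEBV
    accuracy per generation gap); ``r_A_target`` supplies the pedigree
    accuracy per gap (scalar, array, or None for 0).  The returned gamma
    minimizes the squared prediction error over gaps, searched on
    (0, Me/(kL)).
    """
    required = {"gap", "r_G"}
    if not required <= set(observed.columns):
        raise ValueError(f"observed table needs columns {sorted(required)}")
    gaps = observed["gap"].to_numpy()
    if len(gaps) < 1:
        raise ValueError("at least one generation gap is required")
    r_obs = observed["r_G"].to_numpy(dtype=float)
    if r_A_target is None:
        r_A = np.zeros(len(gaps))
    else:
        r_A = np.broadcast_to(np.asarray(r_A_target, dtype=float), (len(gaps),))

    kL = ctx_base.k * ctx_base.L
    upper = ctx_base.Me / kL

    def objective(gamma: float) -> float:
        import dataclasses

        ctx = dataclasses.replace(ctx_base, gamma=gamma)
        err = 0.0
        for gap, ra, ro in zip(gaps, r_A, r_obs):
            pred = ac.predict_target_accuracy(
                r_D_ref, ra, ctx, ac.DistanceToReference(int(gap), int(gap)),
                combine=combine,
            )
            err += (pred.r_G - ro) ** 2
        return err

    lo, hi = 1e-6, upper * (1.0 - 1e-9)
    span = objective(lo) - objective(hi)
    if len(gaps) == 1 and gaps[0] <= 1:
        warnings.warn(
            "a single one-generation gap barely constrains gamma (p_rt is "
            "close to 1); the calibration is ill-conditioned",
            stacklevel=2,
        )
    if abs(span) < 1e-16 and abs(objective(lo) - objective(0.5 * (lo + hi))) < 1e-16:
        raise ValueError("objective is flat: observed accuracies do not vary")
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    return float(res.x)
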