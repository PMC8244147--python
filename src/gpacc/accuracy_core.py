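"""Closed-form accuracy algebra for genomic prediction in closed populations.

The accuracy of genomic estimated breeding values (GEBV, accuracy ``r_G``) is
modelled as a combination of two sources with independent sampling errors:

* pedigree information (PEBV, accuracy ``r_A``), and
* genomic-relationships-deviated-from-pedigree information (DEBV, accuracy
  ``r_D``).

Two equivalent bookkeeping systems connect the three accuracies:

* the **Fisher** route, which maps each squared accuracy to a Fisher
  information statistic ``theta`` (additive over independent sources), and
* the **Index** route, which combines accuracies with selection-index
  weights.

Both routes expose an estimator of the effective number of chromosome
segments ``Me`` of the reference population from observed (r_A, r_G), and
``Me`` in turn drives the erosion of DEBV accuracy from the reference to the
target population through the no-recombination probability ``p_rt``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

from scipy.optimize import brentq

__all__ = [
    "PredictionContext",
    "AccuracySet",
    "ThetaSet",
    "DistanceToReference",
    "VarianceState",
    "q2_from_me",
    "theta_from_r2",
    "r2_from_theta",
    "fisher_combine",
    "fisher_extract",
    "index_combine_r2",
    "index_extract_rD2",
    "me_fisher",
    "me_fisher_from_theta_d",
    "me_index",
    "me_theoretical",
    "p_rt",
    "predict_reference_accuracy",
    "predict_target_accuracy",
    "selection_adjusted_r2",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionContext:
    """Scalar population parameters consumed by the accuracy formulas.

    Parameters
    ----------
    h2:
        Narrow-sense heritability of the training phenotypes, in (0, 1].
    N:
        Size of the reference (training) population.
    M:
        Number of genotyped markers.
    Me:
        Effective number of chromosome segments in the reference population.
    Ne:
        Effective population size (optional, only used by the theoretical
        ``Me`` formulas).
    k:
        Number of chromosomes.
    L:
        Chromosome length in Morgan (``k * L`` is the total map length).
    gamma:
        Segment-size inflation factor of the erosion model.  The default of 2
        doubles the average segment size, accounting for co-segregation
        information eroding faster than linkage-disequilibrium information.
    q2:
        Proportion of genetic variance captured by the marker panel for the
        DEBV component.  For PEBV and GEBV the corresponding proportion is 1
        because both carry pedigree information covering the whole genome.
    """

    h2: float
    N: float
    M: float
    Me: float
    Ne: Optional[float] = None
    k: int = 9
    L: float = 1.5
    gamma: float = 2.0
    q2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if self.Me <= 0:
            raise ValueError(f"Me must be > 0, got {self.Me}")
        if not (0.0 < self.q2 <= 1.0):
            raise ValueError(f"q2 must be in (0, 1], got {self.q2}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.L <= 0:
            raise ValueError(f"L must be > 0, got {self.L}")


@dataclass(frozen=True)
class AccuracySet:
    """Accuracies of the three EBV kinds in one population (reference or target)."""

    r_A: float
    r_D: float
    r_G: float
    scope: Literal["reference", "target"] = "reference"

    def __post_init__(self) -> None:
        for name, value in (("r_A", self.r_A), ("r_D", self.r_D), ("r_G", self.r_G)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ThetaSet:
    """Fisher information statistics of the three EBV kinds; theta_G = theta_A + theta_D."""

    theta_A: float
    theta_D: float
    theta_G: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.theta_A < 0 or self.theta_D < 0:
            raise ValueError("Fisher information statistics must be >= 0")
        if math.isnan(self.theta_G):
            object.__setattr__(self, "theta_G", self.theta_A + self.theta_D)


@dataclass(frozen=True)
class DistanceToReference:
    """Generations between a target individual and its closest reference ancestors.

    ``l_p`` counts on the paternal side, ``l_m`` on the maternal side; both are
    1 when target individuals are progeny of the reference population, 0 when
    the individual is itself part of the reference.
    """

    l_p: int
    l_m: int

    def __post_init__(self) -> None:
        if self.l_p < 0 or self.l_m < 0:
            raise ValueError("generation distances must be non-negative integers")
        if self.l_p != int(self.l_p) or self.l_m != int(self.l_m):
            raise ValueError("generation distances must be integers")

    @property
    def total(self) -> int:
        return int(self.l_p + self.l_m)


@dataclass(frozen=True)
class VarianceState:
    """Genetic variance before (``sigma2_G``) and under (``sigma2_G_sel``) selection."""

    sigma2_G: float
    sigma2_G_sel: float

    def __post_init__(self) -> None:
        if self.sigma2_G <= 0 or self.sigma2_G_sel <= 0:
            raise ValueError("genetic variances must be > 0")

    @property
    def ratio(self) -> float:
        """Selected-to-base variance ratio sigma'^2_G / sigma^2_G."""
        return self.sigma2_G_sel / self.sigma2_G


# ---------------------------------------------------------------------------
# theta <-> r^2 conversions
# ---------------------------------------------------------------------------


def q2_from_me(M: float, Me: float) -> float:
    """Proportion of genetic variance captured by M markers, ``M / (M + Me)``.

    Valid when the minor-allele-frequency distribution of markers matches that
    of the QTL; equals 1 when ``Me`` is 0 (no segment dilution).
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    if Me < 0:
        raise ValueError(f"Me must be >= 0, got {Me}")
    return M / (M + Me)


def theta_from_r2(r2: float, q2: float, h2: float) -> float:
    """Fisher information statistic of an EBV with squared accuracy ``r2``.

    ``theta = r2 * (1 - r2 * q2 * h2) / (q2 - r2)``; strictly increasing in
    ``r2`` on [0, q2) and divergent as ``r2 -> q2``.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    if not (0.0 < q2 <= 1.0):
        raise ValueError(f"q2 must be in (0, 1], got {q2}")
    if r2 < 0:
        raise ValueError(f"r2 must be >= 0, got {r2}")
    if r2 >= q2:
        raise ValueError(
            f"r2 ({r2}) must be < q2 ({q2}): information diverges at the bound"
        )
    return r2 * (1.0 - r2 * q2 * h2) / (q2 - r2)


def r2_from_theta(theta: float, q2: float, h2: float) -> float:
    """Squared accuracy from a Fisher information statistic (inverse of
    :func:`theta_from_r2`).

    Solves the quadratic ``q2*h2*r^4 + (-1 - theta)*r^2 + q2*theta = 0`` for
    its smaller root; monotone increasing in ``theta`` with limit ``q2``.
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    if not (0.0 < q2 <= 1.0):
        raise ValueError(f"q2 must be in (0, 1], got {q2}")
    disc = (1.0 + theta) ** 2 - 4.0 * h2 * q2**2 * theta
    # disc >= (1 - theta)^2 >= 0 because h2*q2^2 <= 1; clip rounding noise
    disc = max(disc, 0.0)
    return (1.0 + theta - math.sqrt(disc)) / (2.0 * q2 * h2)


def fisher_combine(theta_A: float, theta_D: float) -> float:
    """Total Fisher information of GEBV from independent pedigree and DEBV parts."""
    if theta_A < 0 or theta_D < 0:
        raise ValueError("Fisher information statistics must be >= 0")
    return theta_A + theta_D


def fisher_extract(theta_G: float, theta_A: float) -> float:
    """DEBV Fisher information ``theta_G - theta_A`` (must be non-negative)."""
    if theta_G < 0 or theta_A < 0:
        raise ValueError("Fisher information statistics must be >= 0")
    return theta_G - theta_A


# ---------------------------------------------------------------------------
# selection index combination / extraction
# ---------------------------------------------------------------------------


def index_combine_r2(r_A2: float, r_D2: float) -> float:
    """Squared accuracy of the optimal index of PEBV and DEBV.

    ``r_G^2 = (r_A^2 + r_D^2 - 2 r_A^2 r_D^2) / (1 - r_A^2 r_D^2)``, assuming
    independent sampling errors; symmetric and never below max(r_A^2, r_D^2).
    """
    for name, value in (("r_A2", r_A2), ("r_D2", r_D2)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    denom = 1.0 - r_A2 * r_D2
    if denom == 0.0:  # only when both are exactly 1
        return 1.0
    return (r_A2 + r_D2 - 2.0 * r_A2 * r_D2) / denom


def index_extract_rD2(
    r_G2: float, r_A2: float, policy: Literal["clamp", "strict"] = "clamp"
) -> float:
    """DEBV squared accuracy implied by observed GEBV and PEBV accuracies.

    ``r_D^2 = (r_G^2 - r_A^2) / (1 + r_A^2 (r_G^2 - 2))``; exact inverse of
    :func:`index_combine_r2` in its second argument.  When sampling noise
    yields ``r_G2 < r_A2`` the result is clamped to 0 with a warning
    (``policy='clamp'``, default) or a ``ValueError`` is raised
    (``policy='strict'``).
    """
    for name, value in (("r_G2", r_G2), ("r_A2", r_A2)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    if r_G2 < r_A2:
        if policy == "strict":
            raise ValueError(
                f"r_G2 ({r_G2}) < r_A2 ({r_A2}): genomic EBV cannot be less "
                "accurate than pedigree EBV except by sampling noise"
            )
        warnings.warn(
            f"r_G2 ({r_G2:.4g}) < r_A2 ({r_A2:.4g}); clamping r_D2 to 0",
            stacklevel=2,
        )
        return 0.0
    denom = 1.0 + r_A2 * (r_G2 - 2.0)
    if denom <= 0.0:  # r_A2 == 1 and r_G2 < 1 is excluded by r_G2 >= r_A2
        return 1.0
    return (r_G2 - r_A2) / denom


# ---------------------------------------------------------------------------
# Me estimators
# ---------------------------------------------------------------------------


def me_fisher_from_theta_d(theta_D: float, h2: float, N: float, M: float) -> float:
    """Positive root of ``theta_D*Me^2 + theta_D*M*Me - N*M*h2 = 0``."""
    if theta_D <= 0:
        raise ValueError(f"theta_D must be > 0 to define Me, got {theta_D}")
    if N <= 0 or M <= 0:
        raise ValueError("N and M must be > 0")
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    return (
        -theta_D * M + math.sqrt(theta_D**2 * M**2 + 4.0 * theta_D * N * M * h2)
    ) / (2.0 * theta_D)


def me_fisher(r_G: float, r_A: float, h2: float, N: float, M: float) -> float:
    """Effective number of chromosome segments via the Fisher route.

    Converts the observed reference accuracies to Fisher information with
    ``q2 = 1`` (both GEBV and PEBV carry whole-genome pedigree information),
    extracts ``theta_D = theta_G - theta_A`` and solves the quadratic that
    couples ``theta_D`` to ``Me`` through ``q_D^2 = M/(M+Me)``.
    """
    if not (0.0 <= r_A <= 1.0 and 0.0 <= r_G <= 1.0):
        raise ValueError("accuracies must be in [0, 1]")
    if r_G <= r_A:
        raise ValueError(
            f"r_G ({r_G}) must exceed r_A ({r_A}): otherwise theta_D <= 0 and "
            "Me is undefined"
        )
    theta_G = theta_from_r2(r_G**2, 1.0, h2)
    theta_A = theta_from_r2(r_A**2, 1.0, h2)
    return me_fisher_from_theta_d(theta_G - theta_A, h2, N, M)


def me_index(
    r_D: float,
    h2: float,
    N: float,
    M: float,
    *,
    fixed_q2: Optional[float] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> Tuple[float, float]:
    """Effective number of chromosome segments via the Index route.

    Solves the coupled system ``Me = N * q2 * h2 / theta_D(r_D^2, q2, h2)``
    with ``q2 = M / (M + Me)`` by damped fixed-point iteration (successive
    averaging; the undamped iteration oscillates), falling back to bracketed
    root finding if the iteration has not converged.  With ``fixed_q2`` given
    (e.g. 1 for a dense panel) the one-shot closed form is returned instead.

    Returns
    -------
    (Me, q2):
        the converged segment number and the implied marker-capture q2.
    """
    if not (0.0 < r_D < 1.0):
        raise ValueError(f"r_D must be in (0, 1), got {r_D}")
    if N <= 0 or M <= 0:
        raise ValueError("N and M must be > 0")
    r2 = r_D**2

    if fixed_q2 is not None:
        theta_D = theta_from_r2(r2, fixed_q2, h2)
        return N * fixed_q2 * h2 / theta_D, fixed_q2

    def step(me: float) -> float:
        q2 = q2_from_me(M, me)
        if r2 >= q2:
            raise ValueError(
                f"r_D^2 ({r2:.4g}) >= q2 ({q2:.4g}) at Me={me:.4g}: the marker "
                "panel cannot support the observed DEBV accuracy"
            )
        return N * q2 * h2 / theta_from_r2(r2, q2, h2)

    # q2 > r2 requires Me < M*(1 - r2)/r2; the solution always lies inside
    me_sup = M * (1.0 - r2) / r2
    me = min(step(1.0), 0.5 * me_sup)
    converged = False
    try:
        for _ in range(max_iter):
            new = 0.5 * (me + step(me))
            if abs(new - me) <= tol * max(new, 1.0):
                me = new
                converged = True
                break
            me = new
    except ValueError:
        converged = False

    if not converged:
        me = brentq(
            lambda x: x - step(x),
            1e-6,
            me_sup * (1.0 - 1e-12),
            xtol=1e-10,
            rtol=1e-12,
        )
        resid = abs(me - step(me)) / max(me, 1.0)
        if resid > tol:
            raise RuntimeError(
                f"Me iteration failed to converge: relative residual {resid:.3g}"
            )
    return me, q2_from_me(M, me)


def me_theoretical(
    Ne: float, L: float, k: int, variant: Literal["plain", "log_corrected"] = "plain"
) -> float:
    """Theoretical ``Me`` from effective population size and genome size.

    ``plain`` gives ``2*Ne*L*k``; ``log_corrected`` gives
    ``2*Ne*L*k / ln(Ne*L)``.
    """
    if Ne <= 0 or L <= 0 or k <= 0:
        raise ValueError("Ne, L and k must be > 0")
    base = 2.0 * Ne * L * k
    if variant == "plain":
        return base
    if variant == "log_corrected":
        if Ne * L <= 1.0:
            raise ValueError(f"Ne*L must exceed 1 for the log correction, got {Ne * L}")
        return base / math.log(Ne * L)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# accuracy erosion and target prediction
# ---------------------------------------------------------------------------


def p_rt(
    Me: float, k: int, L: float, gamma: float, dist: DistanceToReference
) -> float:
    """Retention of DEBV accuracy from the reference to a target individual.

    Probability that both the paternal and maternal haplotype of an average
    independent segment (size ``gamma*k*L/Me`` Morgan) reach the target
    individual unrecombined from its closest reference ancestors:
    ``(1 - gamma*k*L/Me) ** (l_p + l_m)``.  If the inflated segment covers the
    whole map (``gamma*k*L >= Me``) the segment certainly recombines and 0 is
    returned with a warning.
    """
    if Me <= 0 or gamma <= 0 or k <= 0 or L <= 0:
        raise ValueError("Me, gamma, k and L must be > 0")
    if dist.total == 0:
        return 1.0
    frac = gamma * k * L / Me
    if frac >= 1.0:
        warnings.warn(
            f"gamma*k*L ({gamma * k * L:.4g}) >= Me ({Me:.4g}): average segment "
            "certainly recombined; returning p_rt = 0",
            stacklevel=2,
        )
        return 0.0
    return (1.0 - frac) ** dist.total


def predict_reference_accuracy(
    r_A_ref: float,
    ctx: PredictionContext,
    combine: Literal["fisher", "index"] = "index",
) -> AccuracySet:
    """Predicted accuracies in the reference population given ``Me``.

    DEBV accuracy follows from the information content of the reference data,
    ``theta_D = N * q2 * h2 / Me`` with ``q2 = M/(M+Me)``, and is combined
    with the pedigree accuracy by the requested route.
    """
    q2 = q2_from_me(ctx.M, ctx.Me)
    theta_D = ctx.N * q2 * ctx.h2 / ctx.Me
    r_D2 = r2_from_theta(theta_D, q2, ctx.h2)
    return _combine(r_A_ref, math.sqrt(r_D2), q2, ctx.h2, combine, "reference")


def predict_target_accuracy(
    r_D_ref: float,
    r_A_target: float,
    ctx: PredictionContext,
    dist: DistanceToReference,
    combine: Literal["fisher", "index"] = "index",
) -> AccuracySet:
    """Predicted accuracies of selection candidates in the target population.

    DEBV accuracy erodes multiplicatively, ``r_Dt = p_rt * r_Dr``, and is then
    combined with the (user-supplied or simulator-derived) pedigree accuracy
    of the target individuals by the Fisher or Index route.
    """
    if not (0.0 <= r_D_ref <= 1.0 and 0.0 <= r_A_target <= 1.0):
        raise ValueError("accuracies must be in [0, 1]")
    p = p_rt(ctx.Me, ctx.k, ctx.L, ctx.gamma, dist)
    r_D_t = p * r_D_ref
    q2 = q2_from_me(ctx.M, ctx.Me)
    return _combine(r_A_target, r_D_t, q2, ctx.h2, combine, "target")


def _combine(
    r_A: float,
    r_D: float,
    q2_D: float,
    h2: float,
    combine: Literal["fisher", "index"],
    scope: Literal["reference", "target"],
) -> AccuracySet:
    if combine == "index":
        r_G2 = index_combine_r2(r_A**2, r_D**2)
    elif combine == "fisher":
        theta_A = theta_from_r2(r_A**2, 1.0, h2)
        # the DEBV information is expressed on its own q2_D scale
        r_D2 = min(r_D**2, q2_D * (1.0 - 1e-12))
        theta_D = theta_from_r2(r_D2, q2_D, h2)
        r_G2 = r2_from_theta(theta_A + theta_D, 1.0, h2)
    else:
        raise ValueError(f"unknown combine route {combine!r}")
    return AccuracySet(
        r_A=r_A, r_D=r_D, r_G=math.sqrt(min(max(r_G2, 0.0), 1.0)), scope=scope
    )


def selection_adjusted_r2(r_prime2: float, vs: VarianceState) -> float:
    """Accuracy in a selected population from the unselected-population accuracy.

    ``r^2 = 1 - (1 - r'^2) * sigma'^2_G / sigma^2_G``; valid under the
    infinitesimal model where the prediction error variance is unaffected by
    selection.  An inconsistent variance ratio (yielding r^2 < 0) raises.
    """
    if not (0.0 <= r_prime2 <= 1.0):
        raise ValueError(f"r_prime2 must be in [0, 1], got {r_prime2}")
    r2 = 1.0 - (1.0 - r_prime2) * vs.ratio
    if r2 < 0.0:
        raise ValueError(
            f"selection adjustment gave r^2 = {r2:.4g} < 0: variance ratio "
            f"{vs.ratio:.4g} is inconsistent with r'^2 = {r_prime2:.4g}"
        )
    return r2
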