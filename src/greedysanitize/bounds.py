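"""Closed-form privacy guarantees for locally optimal publishing policies.

A classifier set H is a *local optimum* when adding the attacker's best
classifier h_A does not reduce the publisher's loss T(H) = L*FN + C*FP.
Local optima are characterized by TP(h_A, P) = 0 or FP/TP >= L/C, which
yields, with alpha the sensitive fraction and n the corpus size:

* attacker true-positive bound:   TP_A <= (C/L) (1 - alpha) n
* utility-ratio bound:            U*_A/U_A <= ((1 - alpha) n + 1) / (1 + L/C)
  (valid when the attacker benefits from positives-first ranking,
  TP_A*TN_A >= FP_A*FN_A, and the budget covers the positives,
  B >= TP_A + FP_A).

The finite-sample versions replace the exact local-optimality of h_A with
the empirical one of the publisher's last trained candidate, paying a
VC-dimension deviation term

    lambda(delta, m) = sqrt( (4/m) (v ln(2 e m / v) + ln(4/delta)) )

at residual training size m and confidence 1 - delta, under count-ratio
assumptions FP^ <= p FN^, TP^ >= q N^+, FP_A >= s FN_A, TP_A <= r N_+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .corpus import ConfusionCounts
from .sanitize import GameParams

__all__ = [
    "FiniteSampleParams",
    "BoundReport",
    "BoundValidityError",
    "local_optimum_check",
    "tp_bound",
    "ratio_bound",
    "lambda_bound",
    "fs_tp_bound",
    "fs_ratio_bound",
    "lemma_identities",
    "bound_report",
]

Key = tuple[str, int]


class BoundValidityError(ValueError):
    """Raised when a finite-sample bound's validity condition fails."""


@dataclass(frozen=True)
class FiniteSampleParams:
    """Inputs to the finite-sample bounds.

    vc_dim is the VC dimension v of the hypothesis class; delta the failure
    probability; m the residual training size; p, q, r, s the count-ratio
    constants (FP^ <= p*FN^, TP^ >= q*N^+ on training; FP_A >= s*FN_A,
    TP_A <= r*N_+ on published data).
    """

    vc_dim: int
    delta: float
    m: int
    p: float = math.inf
    q: float = 1.0
    r: float = 1.0
    s: float = math.inf

    def __post_init__(self) -> None:
        if self.vc_dim < 1 or int(self.vc_dim) != self.vc_dim:
            raise ValueError("vc_dim must be an integer >= 1")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError("m must be an integer >= 1")
        if min(self.p, self.q, self.r, self.s) <= 0:
            raise ValueError("p, q, r, s must be > 0")


def local_optimum_check(attacker_counts: ConfusionCounts,
                        params: GameParams) -> bool:
    """True iff the counts witness local optimality: TP=0 or FP/TP >= L/C."""
    tp, fp = attacker_counts.tp, attacker_counts.fp
    return tp == 0 or fp / tp >= params.loss_ratio


def tp_bound(params: GameParams, alpha: float, n: int) -> float:
    """Upper bound on attacker true positives at any local optimum."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    return (params.C / params.L) * (1 - alpha) * n


def ratio_bound(params: GameParams, alpha: float, n: int) -> float:
    """Upper bound on U*_A/U_A at any local optimum (surplus-budget regime).

    The caller is responsible for the preconditions (ranking condition
    TP_A*TN_A >= FP_A*FN_A and budget B >= TP_A + FP_A); see :func:`bound_report`,
    which flags them.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    return ((1 - alpha) * n + 1) / (1 + params.loss_ratio)


def lambda_bound(fsp: FiniteSampleParams) -> float:
    """VC deviation term lambda(delta, m) linking empirical and true error."""
    v, m, delta = fsp.vc_dim, fsp.m, fsp.delta
    return math.sqrt((4.0 / m) * (v * math.log(2 * math.e * m / v)
                                  + math.log(4.0 / delta)))


def _fs_denominator(fsp: FiniteSampleParams, params: GameParams,
                    lam: float | None = None) -> float:
    if lam is None:
        lam = lambda_bound(fsp)
    main = (1 + 1 / fsp.p) * fsp.q * params.loss_ratio
    if lam >= main:
        raise BoundValidityError(
            f"finite-sample bound invalid: lambda(delta,m)={lam:.4g} >= "
            f"(1+1/p) q L/C = {main:.4g}; increase m or loosen delta")
    return main - lam


def fs_tp_bound(fsp: FiniteSampleParams, params: GameParams,
                alpha: float, n: int, lam: float | None = None) -> float:
    """Finite-sample attacker true-positive bound (probability >= 1 - delta).

    Reduces to the asymptotic bound as m -> inf (lambda -> 0) with
    p, s -> inf and q, r -> 1.  ``lam`` overrides the computed deviation
    term, mainly for limit analysis.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    denom = _fs_denominator(fsp, params, lam)
    return fsp.r * (1 + 1 / fsp.s) * (1 - alpha) * n / denom


def fs_ratio_bound(fsp: FiniteSampleParams, params: GameParams,
                   alpha: float, n: int, lam: float | None = None) -> float:
    """Finite-sample utility-ratio bound (probability >= 1 - delta)."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    denom = _fs_denominator(fsp, params, lam)
    rr = fsp.r * (1 + 1 / fsp.s)
    return ((1 - alpha) * n + 1) * rr / (rr + denom)


# ---------------------------------------------------------------------------
# Exact set identities
# ---------------------------------------------------------------------------

def lemma_identities(
    H_predictions: list[dict[Key, int]],
    h_predictions: dict[Key, int],
    labels: dict[Key, int],
) -> bool:
    """Verify the count decompositions used by the stopping rule.

    For any classifier set H and candidate h, with P(H) the instances no
    member of H predicts positive:

        FN(H) = FN(H u h) + TP(h, P(H))
        FP(H u h) = FP(H) + FP(h, P(H))

    Counts follow the set definitions exactly (FN(H) intersects over
    members; FP(H) unions over members).
    """
    universe = set(labels)
    for preds in [*H_predictions, h_predictions]:
        if set(preds) != universe:
            raise ValueError("every classifier must predict the full universe")

    def x1(preds_list: list[dict[Key, int]]) -> set[Key]:
        out: set[Key] = set()
        for preds in preds_list:
            out |= {k for k, p in preds.items() if p == 1}
        return out

    sens = {k for k, lab in labels.items() if lab == 1}
    nonsens = universe - sens

    fn_H = len(sens - x1(H_predictions))
    fp_H = len(nonsens & x1(H_predictions))
    P_H = universe - x1(H_predictions)
    fn_Hh = len(sens - x1([*H_predictions, h_predictions]))
    fp_Hh = len(nonsens & x1([*H_predictions, h_predictions]))
    tp_h_P = len({k for k in P_H & sens if h_predictions[k] == 1})
    fp_h_P = len({k for k in P_H & nonsens if h_predictions[k] == 1})

    return fn_H == fn_Hh + tp_h_P and fp_Hh == fp_H + fp_h_P


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass
class BoundReport:
    """All computed guarantees for one sanitize-and-attack outcome.

    Ratio constants not supplied are estimated from data: p and q from the
    final training-iteration counts (p = FP^/FN^, q = TP^/(TP^+FN^)), and
    r, s from the attacker's counts on published data (r = TP_A/(TP_A+FN_A),
    s = FP_A/FN_A).  ``preconditions_met`` flags, in order, the positives-first
    ranking condition, the surplus-budget regime, and lambda-validity.
    """

    local_optimum: bool
    tp_bound: float
    ratio_bound: float
    lambda_: float | None
    fs_tp_bound: float | None
    fs_ratio_bound: float | None
    preconditions_met: dict[str, bool]
    fsp: FiniteSampleParams | None
    alpha: float
    n: int

    def to_dict(self) -> dict:
        return {
            "local_optimum": self.local_optimum,
            "tp_bound": self.tp_bound,
            "ratio_bound": self.ratio_bound,
            "lambda": self.lambda_,
            "fs_tp_bound": self.fs_tp_bound,
            "fs_ratio_bound": self.fs_ratio_bound,
            "preconditions_met": dict(self.preconditions_met),
            "alpha": self.alpha,
            "n": self.n,
        }


def bound_report(
    attacker_counts: ConfusionCounts,
    params: GameParams,
    alpha: float,
    n: int,
    fsp: FiniteSampleParams | None = None,
) -> BoundReport:
    """Compute every applicable guarantee and flag its preconditions."""
    c = attacker_counts
    pre = {
        "ranking_condition": c.tp * c.tn >= c.fp * c.fn,
        "surplus_budget": params.B >= c.tp + c.fp,
        "lambda_valid": False,
    }
    lam = fs_tp = fs_ratio = None
    if fsp is not None:
        lam = lambda_bound(fsp)
        try:
            fs_tp = fs_tp_bound(fsp, params, alpha, n)
            fs_ratio = fs_ratio_bound(fsp, params, alpha, n)
            pre["lambda_valid"] = True
        except BoundValidityError:
            pass
    return BoundReport(
        local_optimum=local_optimum_check(c, params),
        tp_bound=tp_bound(params, alpha, n),
        ratio_bound=ratio_bound(params, alpha, n),
        lambda_=lam,
        fs_tp_bound=fs_tp,
        fs_ratio_bound=fs_ratio,
        preconditions_met=pre,
        fsp=fsp,
        alpha=alpha,
        n=n,
    )
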