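"""Selection indexes with economic weights, and market profit functions.

The selection index combines predicted direct (DGE) and indirect (IGE)
breeding values for ADG and BF:

    I = W_ADG * (W_DGE * d_ADG + W_IGE * m * s_ADG)
      - W_BF  * (W_DGE * d_BF  + W_IGE * m * s_BF)

with m = pen size - 1 (default 7) the number of pen mates an animal's IGE is
exerted on.  BF enters negatively: leaner is better.  Under the classical
animal model the effect weights are moot and I = W_ADG * u_ADG - W_BF * u_BF.

Profit per pig for a market is

    B = FBW * P_BW - (P_pl + FCR * (FBW - IBW) * P_fd + P_fx * (FBW - IBW) / ADG)
        - penalty(BF)

with final body weight FBW = 110 kg, initial weight IBW = 20 kg, carcass
price 1.164 EUR/kg, piglet price 35 EUR, feed price 0.252 EUR/kg and fixed
daily cost 0.09 EUR/d.  Markets: B1 no BF constraint, B2 lean (penalised
outside 6-10 mm), B3 fat (outside 10-20 mm).  The published penalty rate,
0.012 EUR per mm outside the band, is interpreted as a price reduction per kg
of final body weight, i.e. 0.012 * FBW EUR per pig per mm; a flat per-pig
variant is available via ``per_kg_penalty=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

DEFAULT_PEN_MATES = 7


@dataclass(frozen=True)
class IndexWeights:
    """Economic weights: trait pair sums to 1, effect pair sums to 1."""

    w_adg: float
    w_bf: float
    w_dge: float = 1.0
    w_ige: float = 0.0
    pen_mates: int = DEFAULT_PEN_MATES

    def __post_init__(self):
        for v in (self.w_adg, self.w_bf, self.w_dge, self.w_ige):
            if not 0.0 <= v <= 1.0:
                raise ValueError("weights must lie in [0, 1]")
        if abs(self.w_adg + self.w_bf - 1.0) > 1e-9:
            raise ValueError("trait weights must sum to 1")
        if abs(self.w_dge + self.w_ige - 1.0) > 1e-9:
            raise ValueError("effect weights must sum to 1")


@dataclass(frozen=True)
class ProfitParams:
    fbw: float = 110.0          # final body weight, kg
    ibw: float = 20.0           # initial body weight, kg
    p_bw: float = 1.164         # price per kg live weight, EUR
    p_piglet: float = 35.0      # piglet cost, EUR
    p_feed: float = 0.252       # feed price, EUR/kg
    p_fixed: float = 0.09       # fixed daily cost, EUR/d
    penalty_rate: float = 0.012  # price reduction per BF mm outside band, EUR/kg
    per_kg_penalty: bool = True  # scale penalty by FBW (EUR/kg/mm) vs flat EUR/mm
    ranges: dict = field(
        default_factory=lambda: {"B1": None, "B2": (6.0, 10.0), "B3": (10.0, 20.0)}
    )


def index_value(w: IndexWeights, model: str, dhat_adg=None, shat_adg=None,
                dhat_bf=None, shat_bf=None, uhat_adg=None, uhat_bf=None,
                trait_sd=None):
    """Selection-index value(s); accepts scalars or aligned arrays.

    ``model`` is 'sam' (needs d and s predictions for ADG and BF) or 'am'
    (needs single EBVs; effect weights are ignored).  When ``trait_sd`` =
    (sd_adg, sd_bf) is given, each trait's genetic aggregate is divided by it
    so the percentage weights express relative emphasis on a common scale
    (the breeding program standardizes by the total-breeding-value SD).
    """
    sa, sb = (1.0, 1.0) if trait_sd is None else trait_sd
    if model == "sam":
        if any(v is None for v in (dhat_adg, shat_adg, dhat_bf, shat_bf)):
            raise ValueError("SAM index requires d and s predictions for ADG and BF")
        m = w.pen_mates
        return (
            w.w_adg * (w.w_dge * np.asarray(dhat_adg) + w.w_ige * m * np.asarray(shat_adg)) / sa
            - w.w_bf * (w.w_dge * np.asarray(dhat_bf) + w.w_ige * m * np.asarray(shat_bf)) / sb
        )
    if model == "am":
        if uhat_adg is None or uhat_bf is None:
            raise ValueError("AM index requires EBVs for ADG and BF")
        return w.w_adg * np.asarray(uhat_adg) / sa - w.w_bf * np.asarray(uhat_bf) / sb
    raise ValueError(f"unknown model kind {model!r}")


def tbv(d, s, pen_mates: int = DEFAULT_PEN_MATES):
    """Total breeding value d + m s: the heritable impact on the pen."""
    return np.asarray(d) + pen_mates * np.asarray(s)


def true_index(w: IndexWeights, d_adg, s_adg, d_bf, s_bf, trait_sd=None):
    """The index evaluated on true simulated genetic effects."""
    return index_value(w, "sam", d_adg, s_adg, d_bf, s_bf, trait_sd=trait_sd)


def true_index_tbv(w: IndexWeights, d_adg, s_adg, d_bf, s_bf, trait_sd=None):
    """Index on true total breeding values (the AM-evaluation truth)."""
    sa, sb = (1.0, 1.0) if trait_sd is None else trait_sd
    return (w.w_adg * tbv(d_adg, s_adg, w.pen_mates) / sa
            - w.w_bf * tbv(d_bf, s_bf, w.pen_mates) / sb)


def bf_penalty(bf, market: str, p: ProfitParams = ProfitParams()):
    """Per-pig penalty: distance (mm) outside the market's band times the rate."""
    rng = p.ranges[market]
    bf = np.asarray(bf, dtype=float)
    if rng is None:
        return np.zeros_like(bf)
    lo, hi = rng
    dist = np.maximum(lo - bf, 0.0) + np.maximum(bf - hi, 0.0)
    rate = p.penalty_rate * (p.fbw if p.per_kg_penalty else 1.0)
    return rate * dist


def profit(fcr, adg, bf, market: str, p: ProfitParams = ProfitParams()):
    """Profit per pig (EUR) for one of the markets B1, B2, B3."""
    fcr = np.asarray(fcr, dtype=float)
    adg = np.asarray(adg, dtype=float)
    if np.any(adg <= 0):
        raise ValueError("ADG must be positive")
    if np.any(fcr <= 0):
        raise ValueError("FCR must be positive")
    gain = p.fbw - p.ibw
    revenue = p.fbw * p.p_bw
    cost = p.p_piglet + fcr * gain * p.p_feed + p.p_fixed * gain / adg
    return revenue - cost - bf_penalty(bf, market, p)


_LEVELS = ((0.0, 1.0), (0.25, 0.75), (0.5, 0.5), (0.75, 0.25), (1.0, 0.0))


@dataclass(frozen=True)
class Scenario:
    """One cell of the study grid: data generator, evaluator, index weights."""

    generator: str          # 'sam' | 'am'
    evaluator: str          # 'sam-blup' | 'am-reml-blup' | 'am-blup'
    weights: IndexWeights


def scenario_grid(generator: str = "sam", evaluator: str = "sam-blup",
                  pen_mates: int = DEFAULT_PEN_MATES) -> list[Scenario]:
    """The study's weight grid: 25 scenarios for SAM evaluation, 5 for AM.

    Trait-weight levels {0-100, 25-75, 50-50, 75-25, 100-0} crossed with the
    same effect-weight levels under SAM evaluation; trait weights alone when
    the evaluation uses a single EBV per trait.
    """
    out = []
    if evaluator == "sam-blup":
        for (wa, wb), (wd, wi) in product(_LEVELS, _LEVELS):
            out.append(
                Scenario(generator, evaluator,
                         IndexWeights(wa, wb, wd, wi, pen_mates=pen_mates))
            )
    else:
        for wa, wb in _LEVELS:
            out.append(
                Scenario(generator, evaluator,
                         IndexWeights(wa, wb, pen_mates=pen_mates))
            )
    return out
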