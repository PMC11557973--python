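"""Residence-time binding free energies.

The free energy is computed from total bound/unbound residence times as

    dG = -R*T*ln(1/f - 1),   f = t_b / (t_b + t_l)

which equals R*T*ln(t_b / t_l): positive when the bound state dominates.
Two unit conventions are provided. ``paper_literal`` uses R in SI
(8.314 J/mol/K) and divides by 1000 — numerically kJ/mol although the
source labels it kcal/mol; ``kcal`` uses R = 1.987e-3 kcal/mol/K with no
division. Both are carried in summaries so the discrepancy stays visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from pepmem.contacts import StateTrack

R_SI = 8.314            # J / (mol K)
R_KCAL = 1.987204e-3    # kcal / (mol K)

MODE_PAPER = "paper_literal"
MODE_KCAL = "kcal"


class DeltaGUndefinedError(ValueError):
    """Free energy is undefined: the system was never bound or never unbound."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(f"deltaG undefined: {reason}")


@dataclass(frozen=True)
class ThermoParams:
    temperature: float = 333.0          # K
    gas_constant_mode: str = MODE_PAPER

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.gas_constant_mode not in (MODE_PAPER, MODE_KCAL):
            raise ValueError(f"unknown gas_constant_mode {self.gas_constant_mode!r}")

    @property
    def rt_scale(self) -> float:
        """R*T in the selected output unit."""
        if self.gas_constant_mode == MODE_PAPER:
            return R_SI * self.temperature / 1000.0
        return R_KCAL * self.temperature


def delta_g(t_b: float, t_l: float, params: ThermoParams = ThermoParams()) -> float:
    """Residence-time free energy from bound/unbound times (ns).

    Raises DeltaGUndefinedError when either time is zero — a trajectory
    that never binds (or never unbinds) carries no ratio information.
    """
    if t_b < 0 or t_l < 0:
        raise ValueError("residence times must be non-negative")
    if t_b == 0:
        raise DeltaGUndefinedError("never bound (t_b = 0)")
    if t_l == 0:
        raise DeltaGUndefinedError("never unbound (t_l = 0)")
    return params.rt_scale * math.log(t_b / t_l)


@dataclass
class BindingSummary:
    """Per-system residence statistics and free energy.

    ``deltaG`` is in the convention selected by ThermoParams and is None
    when undefined; ``status`` is "ok", "never_bound" or "never_unbound".
    """

    system: str
    n_events: int
    t_b: float                      # ns
    t_l: float                      # ns
    pct_bound: float                # %
    deltaG: Optional[float]
    deltaG_paper: Optional[float]   # paper_literal convention
    deltaG_kcal: Optional[float]    # dimensionally consistent kcal/mol
    status: str

    def to_record(self) -> dict:
        return {
            "system": self.system,
            "n_events": self.n_events,
            "t_b_ns": self.t_b,
            "t_l_ns": self.t_l,
            "pct_bound": self.pct_bound,
            "deltaG": float("nan") if self.deltaG is None else self.deltaG,
            "deltaG_paper": float("nan") if self.deltaG_paper is None else self.deltaG_paper,
            "deltaG_kcal": float("nan") if self.deltaG_kcal is None else self.deltaG_kcal,
            "status": self.status,
        }


def summarize(
    track: StateTrack,
    total_time: float,
    label: str = "system",
    params: ThermoParams = ThermoParams(),
) -> BindingSummary:
    """Aggregate a state track into a BindingSummary.

    Never-bound / never-unbound tracks yield a tagged sentinel record
    (deltaG = None) instead of raising, so batch runs complete.
    """
    t_b = track.t_bound
    t_l = total_time - t_b
    if t_l < -1e-9:
        raise ValueError("total_time is shorter than the tracked bound time")
    t_l = max(t_l, 0.0)
    pct = 100.0 * t_b / (t_b + t_l) if t_b + t_l > 0 else float("nan")
    try:
        g_sel = delta_g(t_b, t_l, params)
        g_paper = delta_g(t_b, t_l, ThermoParams(params.temperature, MODE_PAPER))
        g_kcal = delta_g(t_b, t_l, ThermoParams(params.temperature, MODE_KCAL))
        status = "ok"
    except DeltaGUndefinedError as exc:
        g_sel = g_paper = g_kcal = None
        status = "never_bound" if "never bound" in exc.reason else "never_unbound"
    return BindingSummary(
        system=label,
        n_events=track.n_events,
        t_b=t_b,
        t_l=t_l,
        pct_bound=pct,
        deltaG=g_sel,
        deltaG_paper=g_paper,
        deltaG_kcal=g_kcal,
        status=status,
    )
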