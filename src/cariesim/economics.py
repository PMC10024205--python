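"""Cost and QALY accrual from a health-care perspective, with discounting.

Costs are expressed in 2022 USD; packaged unit costs and disutility weights
are documented order-of-magnitude assumptions.  Annual accrual happens at
cycle end with no half-cycle correction; year 0 is undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass
class EconParams:
    cost_preventive_visit: float = 50.0
    cost_restorative: float = 620.0   # per treated carious event
    cost_abscess: float = 2600.0      # per abscess episode (incl. urgent care)
    cost_extraction: float = 450.0    # per tooth lost
    award_cost: dict = field(
        default_factory=lambda: {"scholarship": 120_000.0,
                                 "loan_repayment": 42_000.0,
                                 "students_to_service": 110_000.0}
    )
    disutility_untreated: float = 0.041  # per year with untreated caries
    disutility_treated: float = 0.005    # per year with treated caries only
    disutility_abscess: float = 0.060    # abscess episode year
    disutility_tooth_loss: float = 0.012 # per year, permanent after loss
    discount_rate: float = 0.03

    def validate(self) -> None:
        for name in ("cost_preventive_visit", "cost_restorative", "cost_abscess",
                     "cost_extraction"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for t, c in self.award_cost.items():
            if c < 0:
                raise ConfigurationError(f"award cost for {t} must be >= 0")
        for name in ("disutility_untreated", "disutility_treated",
                     "disutility_abscess", "disutility_tooth_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} outside [0,1]")
        if self.discount_rate <= -1.0:
            raise ConfigurationError("discount rate must be > -100%")


def discount(value, year, rate: float):
    """Present value of ``value`` accruing ``year`` years from start."""
    if rate <= -1.0:
        raise ConfigurationError("discount rate must be > -100%")
    year = np.asarray(year)
    if (year < 0).any():
        raise ConfigurationError("year index must be >= 0")
    return np.asarray(value) / (1.0 + rate) ** year


def cycle_costs(ec: EconParams, *, utilized=0, treated_events=0, conversions=0,
                abscesses=0, extractions=0):
    """Health-care cost of one cycle's events (scalars or aligned arrays).

    Preventive visit if care was utilized; restorative cost per treated new
    event and per prevalent untreated case converted to treated; abscess
    episode and extraction costs per occurrence.
    """
    return (ec.cost_preventive_visit * np.asarray(utilized, dtype=float)
            + ec.cost_restorative * (np.asarray(treated_events, dtype=float)
                                     + np.asarray(conversions, dtype=float))
            + ec.cost_abscess * np.asarray(abscesses, dtype=float)
            + ec.cost_extraction * np.asarray(extractions, dtype=float))


def cycle_qaly(ec: EconParams, *, alive=1, untreated=0, treated_only=0,
               abscess_episode=0, tooth_loss=0):
    """Utility accrued over one cycle, in [0, 1]; the dead accrue 0.

    ``treated_only`` marks caries experience with no currently untreated
    caries; ``tooth_loss`` is a permanent annual decrement once any tooth is
    lost; ``abscess_episode`` applies only in the episode year.
    """
    u = (1.0
         - ec.disutility_untreated * np.asarray(untreated, dtype=float)
         - ec.disutility_treated * np.asarray(treated_only, dtype=float)
         - ec.disutility_abscess * np.asarray(abscess_episode, dtype=float)
         - ec.disutility_tooth_loss * np.asarray(tooth_loss, dtype=float))
    return np.clip(u, 0.0, 1.0) * np.asarray(alive, dtype=float)


def program_cost(awards: dict, ec: EconParams, rate: float | None = None,
                 commitment_years: dict | None = None,
                 horizon: int | None = None) -> float:
    """Discounted program outlay of an award stream.

    By default the full award cost is paid in the award year.  When
    ``commitment_years`` is given, each award's cost is amortized evenly over
    its service commitment (matching how loan-repayment funds are disbursed)
    and truncated at ``horizon`` years from start, so that costs and in-horizon
    service years line up.
    """
    rate = ec.discount_rate if rate is None else rate
    total = 0.0
    for t, stream_t in awards.items():
        a = np.asarray(stream_t, dtype=float)
        if (a < 0).any():
            raise ConfigurationError(f"negative awards in stream for {t}")
        cost_stream = a * ec.award_cost[t]
        if commitment_years is not None:
            c = int(commitment_years[t])
            cost_stream = np.convolve(cost_stream / c, np.ones(c))
            if horizon is not None:
                cost_stream = cost_stream[:horizon]
        total += float(np.sum(discount(cost_stream, np.arange(len(cost_stream)), rate)))
    return total
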