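"""Population-impact indicators of lifestyle on incident hypertension.

The exposure contrast is lifestyle score 0-3 (exposed, "unfavorable
lifestyle") versus 4-5 (unexposed, "favorable lifestyle"). With incidences
Ie (exposed), Iu (unexposed) and It (total population):

* RR  = Ie / Iu                              relative risk
* AR  = (Ie - Iu) * 100                      attributable risk, percentage points
* PAR = It - Iu                              population attributable risk (proportion)
* PAR% = (It - Iu) / It * 100
* PFP = (Ie - It) / Ie * 100                 prevented fraction for the population,
                                             treating the favorable lifestyle as the
                                             protective exposure whose absence would
                                             leave the whole population at incidence Ie
* morbidities averted = N_total * (Ie - It)  cases already prevented by the current
                                             prevalence of the favorable lifestyle

All values are kept at full precision internally; display rounding (2
decimals, half-up) happens only at output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd


class DegenerateGroupError(ValueError):
    """An indicator denominator is empty or zero."""


@dataclass(frozen=True)
class ExposureCounts:
    exposed_events: int
    exposed_total: int
    unexposed_events: int
    unexposed_total: int

    def __post_init__(self) -> None:
        for name in ("exposed", "unexposed"):
            ev = getattr(self, f"{name}_events")
            tot = getattr(self, f"{name}_total")
            if ev < 0 or tot < 0 or ev > tot:
                raise ValueError(f"invalid counts for {name} group: {ev}/{tot}")


@dataclass(frozen=True)
class EpiIndicators:
    incidence_total: float
    incidence_exposed: float
    incidence_unexposed: float
    rr: float
    ar: float       # percentage points
    par: float      # proportion
    par_pct: float  # percent
    pfp: float      # percent
    morbidities_averted: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Half-up display rounding of every indicator."""
        q = Decimal(10) ** -ndigits
        return {
            k: float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))
            for k, v in asdict(self).items()
        }


def tabulate_exposure(
    scored: pd.DataFrame, stratum: str | None = None
) -> ExposureCounts:
    """Event/total counts for the lifestyle exposure contrast.

    Exposed = lifestyle score 0-3, unexposed = score 4-5, optionally within
    one GRS risk group (``stratum``).
    """
    data = scored
    if stratum is not None:
        data = scored[scored["grs_group"] == stratum]
        if data.empty:
            raise DegenerateGroupError(f"no subjects in GRS stratum {stratum!r}")
    exposed = data["lifestyle_score"] <= 3
    events = data["hypertension"].astype(bool)
    return ExposureCounts(
        exposed_events=int((exposed & events).sum()),
        exposed_total=int(exposed.sum()),
        unexposed_events=int((~exposed & events).sum()),
        unexposed_total=int((~exposed).sum()),
    )


def compute_indicators(
    counts: ExposureCounts, population_total: int, population_events: int
) -> EpiIndicators:
    """Indicator panel from exposure counts and the population totals.

    ``population_total``/``population_events`` are normally the sums of the
    two exposure groups but are passed explicitly so a stratum can carry
    its own totals.
    """
    if counts.exposed_total == 0:
        raise DegenerateGroupError("exposed group is empty; RR/AR/PFP undefined")
    if counts.unexposed_total == 0:
        raise DegenerateGroupError("unexposed group is empty; RR/AR/PAR undefined")
    if population_total <= 0:
        raise DegenerateGroupError("population total must be positive")
    ie = counts.exposed_events / counts.exposed_total
    iu = counts.unexposed_events / counts.unexposed_total
    it = population_events / population_total
    if iu == 0:
        raise DegenerateGroupError("unexposed incidence is zero; RR undefined")
    if it == 0:
        raise DegenerateGroupError("population incidence is zero; PAR%/PFP undefined")
    if ie == 0:
        raise DegenerateGroupError("exposed incidence is zero; PFP undefined")
    return EpiIndicators(
        incidence_total=it,
        incidence_exposed=ie,
        incidence_unexposed=iu,
        rr=ie / iu,
        ar=(ie - iu) * 100.0,
        par=it - iu,
        par_pct=(it - iu) / it * 100.0,
        pfp=(ie - it) / ie * 100.0,
        morbidities_averted=population_total * (ie - it),
    )


def indicator_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Indicator panel overall and per GRS risk group.

    Each stratum column uses its own population totals. Strata whose
    indicator panel is degenerate (e.g. no unexposed subjects) carry NaN
    entries with the reason in the ``note`` column.
    """
    columns = [("overall", scored)] + [
        (g, scored[scored["grs_group"] == g]) for g in ("low", "intermediate", "high")
    ]
    rows = []
    for name, data in columns:
        row: dict = {"stratum": name, "n": int(len(data))}
        if data.empty:
            row["note"] = "empty stratum"
            rows.append(row)
            continue
        row["events"] = int(data["hypertension"].sum())
        try:
            counts = tabulate_exposure(data)
            panel = compute_indicators(counts, len(data), row["events"])
            row.update(
                incidence_pct=panel.incidence_total * 100.0,
                rr=panel.rr,
                ar=panel.ar,
                par=panel.par,
                par_pct=panel.par_pct,
                pfp=panel.pfp,
                morbidities_averted=panel.morbidities_averted,
                note="",
            )
        except DegenerateGroupError as exc:
            row.update(
                incidence_pct=row["events"] / len(data) * 100.0, note=str(exc)
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    # additivity cross-check: stratum averted counts need not sum exactly to
    # the pooled value; both are reported side by side
    strat = table.loc[table["stratum"] != "overall", "morbidities_averted"]
    table.attrs["sum_stratum_averted"] = float(strat.sum(skipna=True))
    return table
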