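"""Table- and figure-style reports over completed evaluations.

Reports are pure views: they only re-arrange numbers already present in
the evaluations and never mutate them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import CostBook, CultivationEvaluation, ValidationError

__all__ = ["cost_breakdown_report", "energy_breakdown_report"]

#: conversion used when heat is reported alongside electricity
KWH_PER_MJ = 1.0 / 3.6


def cost_breakdown_report(evaluations: list[CultivationEvaluation],
                          book: CostBook | None = None) -> pd.DataFrame:
    """Stacked cost components per pot and per m² for each evaluation.

    Per-pot components are the per-m²-day series weighted by the daily
    area per pot and summed, so fixed+electricity+heating+CO2 add up to
    the evaluation's cost per pot exactly; the plant cost is listed as its
    own component on the per-pot side.  Requires full-ledger evaluations.
    """
    book = book or CostBook()
    rows = []
    for e in evaluations:
        if e.ledger is None or "ad" not in e.ledger.columns:
            raise ValidationError(
                f"evaluation {e.team!r} has no daily ledger; the cost "
                "breakdown needs the full-trace path")
        led = e.ledger
        ad = led["ad"].to_numpy(float)
        per_pot = {c: float(np.sum(led[col].to_numpy(float) * ad))
                   for c, col in (("fixed", "F"), ("electricity", "Ld"),
                                  ("heating", "Hd"), ("co2", "Cd"))}
        per_m2 = {f"{c}_per_m2": float(led[col].sum())
                  for c, col in (("fixed", "F"), ("electricity", "Ld"),
                                 ("heating", "Hd"), ("co2", "Cd"))}
        rows.append({
            "team": e.team,
            "plant_cost_per_pot": book.plant_cost,
            **{f"{k}_per_pot": v for k, v in per_pot.items()},
            "total_per_pot": sum(per_pot.values()),
            **per_m2,
            "total_per_m2": sum(per_m2.values()),
        })
    return pd.DataFrame(rows)


def energy_breakdown_report(evaluations: list[CultivationEvaluation]
                            ) -> pd.DataFrame:
    """Electricity and heating energy per m² of greenhouse, kWh.

    Expressed per m² (not per pot) so the numbers are unaffected by plant
    spacing; both carriers are in kWh for direct comparison.
    """
    rows = []
    for e in evaluations:
        if e.ledger is None:
            raise ValidationError(
                f"evaluation {e.team!r} has no daily ledger")
        rows.append({
            "team": e.team,
            "electricity_kwh_per_m2": float(e.ledger["EL"].sum()),
            "heating_kwh_per_m2": float(e.ledger["EH"].sum()),
            "co2_kg_per_m2": float(e.ledger["co2_kg"].sum()),
        })
    return pd.DataFrame(rows)
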