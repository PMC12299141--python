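"""Fruit-based pot pricing, gains per pot, and price-curve calibration.

The dwarf-tomato pot is valued on the day of harvest from three quality
figures: the ripe (red) fruit fresh weight per pot *ffw*, the dry-matter
percentage of the ripe fruit *dmp*, and the ripe fraction of the total
fruit weight *rfp*.  A pot with too few ripe fruits (rfp below one third)
or too little ripe weight (below 50 g) is unsellable.  Otherwise the price
at the 150 g weight cap interpolates linearly on the dry-matter axis
between a low curve (dmp <= 7 %) and a high curve (dmp >= 8 %).

The published price-curve endpoints are known only graphically; the cap
prices can be re-derived from a results table via
:func:`calibrate_price_caps`, which inverts the gains of teams whose
harvests exceeded the weight cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CostBook, PriceModel, ValidationError

__all__ = ["price", "gains_per_pot", "calibrate_price_caps",
           "CapCalibration", "read_calibration_table"]


def _dm_weight(dmp: float, model: PriceModel) -> float:
    """Interpolation weight of the high-price curve at dry matter ``dmp`` %."""
    return float(np.clip((dmp - model.dm_low) / (model.dm_high - model.dm_low),
                         0.0, 1.0))


def price(ffw: float, dmp: float, rfp: float, model: PriceModel) -> float:
    """Price of one pot, EUR.

    Parameters
    ----------
    ffw : ripe fruit fresh weight, g/pot.
    dmp : dry-matter percentage of the ripe fruit, e.g. ``6.8`` for 6.8 %.
    rfp : ripe fraction of the total fruit fresh weight.  Values slightly
        above 1 can occur when red and total weights come from different
        plants; they are clamped to 1 for the sellability gate.
    """
    if ffw < 0 or dmp < 0 or rfp < 0:
        raise ValidationError("price inputs must be >= 0")
    if min(rfp, 1.0) < model.ripeness_min or ffw < model.ffw_min:
        return 0.0
    w = _dm_weight(dmp, model)
    cap_price = (1.0 - w) * model.price_low_at_cap + w * model.price_high_at_cap
    if ffw >= model.ffw_cap or model.sub_cap_shape == "flat":
        return cap_price
    # proportional: price scales linearly through the origin with weight,
    # gated at ffw_min
    return cap_price * ffw / model.ffw_cap


def gains_per_pot(P: float, book: CostBook, interventions: int = 0) -> float:
    """Gains per pot G = price − plant cost (− optional intervention penalty).

    The intervention penalty is an alternate scoring mode and is disabled
    unless ``book.penalty_enabled`` is set.
    """
    if P < 0:
        raise ValidationError("price must be >= 0")
    penalty = (book.intervention_penalty * interventions
               if book.penalty_enabled else 0.0)
    return P - book.plant_cost - penalty


@dataclass
class CapCalibration:
    price_low_at_cap: float
    price_high_at_cap: float
    max_residual: float

    def apply(self, model: PriceModel) -> PriceModel:
        """A copy of ``model`` with the calibrated cap prices."""
        import dataclasses
        return dataclasses.replace(model,
                                   price_low_at_cap=self.price_low_at_cap,
                                   price_high_at_cap=self.price_high_at_cap)


def calibrate_price_caps(rows, model: PriceModel,
                         plant_cost: float = 0.75) -> CapCalibration:
    """Fit the two cap prices from observed (gains, dmp, ffw) rows.

    Every row must have ``ffw >= ffw_cap`` so its price sits on the flat
    part of the weight axis, where
    ``gains + plant_cost = (1−w)·low + w·high`` with
    ``w = clip((dmp − dm_low)/(dm_high − dm_low), 0, 1)``.  The two caps
    are the least-squares solution of that linear system.

    Parameters
    ----------
    rows : iterable of ``(gains, dmp, ffw)`` triples (EUR/pot, %, g/pot).

    Raises
    ------
    ValidationError
        If any row is below the weight cap, or if the system is
        underdetermined (e.g. all rows on the low curve leave the high cap
        free).
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("no calibration rows")
    gains = np.array([r[0] for r in rows], dtype=float)
    dmp = np.array([r[1] for r in rows], dtype=float)
    ffw = np.array([r[2] for r in rows], dtype=float)
    if np.any(ffw < model.ffw_cap):
        raise ValidationError("calibration rows must have ffw >= ffw_cap")
    w = np.clip((dmp - model.dm_low) / (model.dm_high - model.dm_low), 0, 1)
    design = np.column_stack([1.0 - w, w])
    if np.linalg.matrix_rank(design) < 2:
        raise ValidationError(
            "cap prices underdetermined: calibration rows must span both "
            "sides of the dry-matter interpolation")
    target = gains + plant_cost
    sol, *_ = np.linalg.lstsq(design, target, rcond=None)
    residual = design @ sol - target
    return CapCalibration(float(sol[0]), float(sol[1]),
                          float(np.max(np.abs(residual))))


def read_calibration_table(path: str | Path) -> list[tuple[float, float, float]]:
    """Read a ``gains,dmp,ffw`` CSV into calibration rows."""
    df = pd.read_csv(path)
    return [(float(r.gains), float(r.dmp), float(r.ffw))
            for r in df.itertuples()]
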