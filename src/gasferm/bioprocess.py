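"""Biomass conversion, liquid-phase rates and C-mol carbon balancing.

At chemostat steady state the liquid-phase specific production rate of a
broth metabolite follows from the continuous-stirred-tank identity
q_i = D c_i / X (dilution rate D in 1/h, concentration c_i in mM, biomass
X in gDCW/L). Carbon balances compare the C-mol flows of all products
(acetate, ethanol, 2,3-butanediol, CO2, biomass) against the C-mol uptake
of the substrates (CO, optionally cysteine); ethanol stripped into the
off-gas and CO2 dissolved in the broth (CO2* + bicarbonate) are included so
the recovery is not biased low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .offgas import RatePanel

__all__ = [
    "OD_TO_DCW",
    "SpeciesCarbon",
    "CarbonBalance",
    "biomass_from_od",
    "od_from_biomass",
    "liquid_specific_rate",
    "dissolved_co2_rate",
    "carbon_balance",
    "product_ratio",
    "fold_change_table",
]

#: OD600 -> gDCW/L correlation coefficient for C. autoethanogenum
OD_TO_DCW = 0.23

HOURS_PER_DAY = 24.0


class BioprocessError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesCarbon:
    """Carbon atom counts per compound and biomass carbon content.

    ``biomass_cmol`` is C-mol per gDCW; the 0.0417 default corresponds to
    a 24 g/C-mol generic biomass formula (CH1.8O0.5N0.2) and matches the
    precursor draw of the core flux model's biomass reaction.
    """

    counts: Mapping[str, int] = field(default_factory=lambda: {
        "CO": 1, "CO2": 1, "acetate": 2, "ethanol": 2, "2,3-BDO": 4,
        "cysteine": 3})
    biomass_cmol: float = 0.0417

    def carbon(self, species: str) -> int:
        try:
            return self.counts[species]
        except KeyError:
            raise BioprocessError(f"no carbon count for {species!r}") from None


@dataclass
class CarbonBalance:
    """C-mol product fractions of total substrate carbon uptake.

    ``fractions`` are raw (they sum to recovery/100); ``normalised`` is
    rescaled to sum to exactly 100% for fair comparison of carbon
    distributions between conditions.
    """

    fractions: dict[str, float]
    recovery: float        # percent

    @property
    def normalised(self) -> dict[str, float]:
        total = sum(self.fractions.values())
        return {k: 100.0 * v / total for k, v in self.fractions.items()}

    def to_frame(self) -> pd.DataFrame:
        norm = self.normalised
        return pd.DataFrame(
            {"product": list(self.fractions),
             "cmol_fraction": [self.fractions[k] for k in self.fractions],
             "normalised_pct": [norm[k] for k in self.fractions]})


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def biomass_from_od(od600: float, k: float = OD_TO_DCW) -> float:
    """Biomass concentration (gDCW/L) from optical density, X = K * OD."""
    if od600 < 0:
        raise BioprocessError("OD600 cannot be negative")
    return k * od600


def od_from_biomass(biomass: float, k: float = OD_TO_DCW) -> float:
    if biomass < 0:
        raise BioprocessError("biomass cannot be negative")
    return biomass / k


def liquid_specific_rate(conc_mM: float, dilution: float, biomass: float,
                         stripped_q: float = 0.0) -> float:
    """Specific production rate from a broth concentration, mmol/gDCW/h.

    ``dilution`` is in 1/day (converted internally to 1/h); ``stripped_q``
    adds an off-gas-stripped flux (used for ethanol only).
    """
    if dilution <= 0:
        raise BioprocessError("dilution rate must be positive")
    if biomass <= 0:
        raise BioprocessError("biomass must be positive")
    return (dilution / HOURS_PER_DAY) * conc_mM / biomass + stripped_q


def dissolved_co2_rate(pH: float, temperature_C: float,
                       co2_partial_pressure: float, dilution: float,
                       biomass: float, henry_M_atm: float = 0.0246,
                       pKa1: float = 6.30) -> float:
    """Specific rate of soluble CO2 leaving with the liquid outflow.

    Dissolved CO2* follows Henry's law (c = K_H pCO2) and bicarbonate adds
    a factor 10^(pH - pKa1); at the mildly acidic pH of acetogen cultures
    (pH ~5) the bicarbonate correction is only a few percent. The total
    soluble pool exits with the broth at D c_total / X.
    """
    if not 0 < pH < 14:
        raise BioprocessError("pH out of range")
    if co2_partial_pressure < 0:
        raise BioprocessError("partial pressure cannot be negative")
    c_star_M = henry_M_atm * co2_partial_pressure
    c_total_mM = 1000.0 * c_star_M * (1.0 + 10.0 ** (pH - pKa1))
    return liquid_specific_rate(c_total_mM, dilution, biomass)


def carbon_balance(product_rates: Mapping[str, float], mu: float,
                   substrate_rates: Mapping[str, float],
                   carbon: SpeciesCarbon | None = None) -> CarbonBalance:
    """C-mol balance of substrate carbon over growth products.

    ``product_rates``/``substrate_rates`` are positive specific rates
    (mmol/gDCW/h) keyed by species name; ``mu`` (1/day) supplies the
    biomass term (mu/24 * biomass C-mol/gDCW * 1000 mmol C per gDCW/h).
    """
    carbon = carbon or SpeciesCarbon()
    uptake_cmol = sum(q * carbon.carbon(sp)
                      for sp, q in substrate_rates.items())
    if uptake_cmol <= 0:
        raise BioprocessError("total substrate C-mol uptake must be positive")
    fractions = {sp: q * carbon.carbon(sp) / uptake_cmol
                 for sp, q in product_rates.items()}
    fractions["biomass"] = ((mu / HOURS_PER_DAY) * carbon.biomass_cmol
                            * 1000.0 / uptake_cmol)
    recovery = 100.0 * sum(fractions.values())
    return CarbonBalance(fractions=fractions, recovery=recovery)


def product_ratio(q_ace: float, q_etoh: float) -> float:
    """Molar acetate/ethanol ratio."""
    if q_etoh == 0:
        raise BioprocessError("acetate/ethanol ratio undefined at zero ethanol")
    return q_ace / q_etoh


def fold_change_table(panels_by_mu: Mapping[float, RatePanel | Mapping[str, float]]
                      ) -> pd.DataFrame:
    """Fold change of each specific rate between the extreme growth rates.

    ``panels_by_mu`` maps mu (1/day) to a rate panel (or a plain
    species->rate mapping of condition means). Returns the ratio of the
    highest-mu over the lowest-mu rate per species, with a one-decimal
    presentation column; zero denominators are flagged instead of dividing.
    """
    if len(panels_by_mu) < 2:
        raise BioprocessError("fold changes need at least two mu levels")
    mus = sorted(panels_by_mu)
    lo, hi = panels_by_mu[mus[0]], panels_by_mu[mus[-1]]

    def rates(panel):
        return panel.q if isinstance(panel, RatePanel) else dict(panel)

    lo_q, hi_q = rates(lo), rates(hi)
    rows = []
    for sp in sorted(set(lo_q) | set(hi_q)):
        a, b = lo_q.get(sp, np.nan), hi_q.get(sp, np.nan)
        if not a:
            rows.append({"species": sp, "fold_change": np.nan,
                         "fold_change_1dp": np.nan, "flag": "zero-denominator"})
        else:
            fc = b / a
            rows.append({"species": sp, "fold_change": fc,
                         "fold_change_1dp": round(fc, 1), "flag": ""})
    return pd.DataFrame(rows)


def relative_decrease(before: float, after: float) -> float:
    """Relative decrease in percent, e.g. 32.3 -> 13.9 gives ~57."""
    if before == 0:
        raise BioprocessError("undefined relative change from zero")
    return 100.0 * (before - after) / before
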