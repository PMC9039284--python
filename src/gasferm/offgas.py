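"""Off-gas analysis: inert-gas (Ar) balance inversion of bioreactor traces.

A chemostat fed with a CO or syngas blend containing argon as the inert
component changes the total molar gas flow as CO/H2 are consumed and CO2 is
produced. Because argon is neither consumed nor produced, its molar flow is
conserved, which lets the outlet flow be inferred from the inlet flow and
the Ar mole fractions alone. Specific rates (mmol per gram dry cell weight
per hour) then follow from the inlet/outlet molar flows of each species
normalised by the biomass inventory of the reactor.

Flows are volumetric at reference conditions (0 degC, 1 atm by default;
22.414 mL/mmol), configurable via ``molar_volume``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GasStream",
    "RatePanel",
    "MOLAR_VOLUME_STP",
    "SPECIES",
    "infer_outflow",
    "specific_gas_rate",
    "ethanol_stripping_rate",
    "steady_state_window",
    "rates_from_trace",
]

#: mL of ideal gas per mmol at 0 degC, 1 atm
MOLAR_VOLUME_STP = 22.414

#: species tracked in the off-gas (mass-spectrometer channels)
SPECIES = ("CO", "H2", "CO2", "ethanol", "Ar")

#: substrates are taken up; the rest are produced
UPTAKE_SPECIES = frozenset({"CO", "H2"})


class OffgasError(ValueError):
    """Raised for invalid gas-stream inputs."""


@dataclass(frozen=True)
class GasStream:
    """A gas flow with its composition.

    ``flow`` is the volumetric flow (mL/min at reference conditions) and
    ``fractions`` maps species to mole fraction. Fractions must be
    non-negative and sum to <= 1 (unmeasured species may make up the rest);
    for inert-balance use the Ar fraction must be positive.
    """

    flow: float
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flow < 0:
            raise OffgasError("flow must be non-negative")
        for sp, y in self.fractions.items():
            if y < -1e-12:
                raise OffgasError(f"negative mole fraction for {sp}")
        if sum(self.fractions.values()) > 1 + 1e-9:
            raise OffgasError("mole fractions sum to more than 1")

    def fraction(self, species: str) -> float:
        return float(self.fractions.get(species, 0.0))

    def molar_flow(self, species: str,
                   molar_volume: float = MOLAR_VOLUME_STP) -> float:
        """mmol/min of one species."""
        return self.flow * self.fraction(species) / molar_volume


@dataclass
class RatePanel:
    """Specific rates for one steady state, positive magnitudes with roles.

    ``q`` maps species to magnitude (mmol/gDCW/h); ``roles`` maps species to
    "uptake" or "production". Storing magnitudes with explicit role labels
    avoids silent sign errors when a species switches between net uptake and
    net production (CO2 in syngas feeds can do either).
    """

    mu: float                      # 1/day
    q: dict[str, float]
    roles: dict[str, str]
    biomass: float                 # gDCW/L
    working_volume: float          # L

    def __post_init__(self) -> None:
        for sp, val in self.q.items():
            if not np.isfinite(val):
                raise OffgasError(f"non-finite rate for {sp}")

    def signed(self, species: str, production_positive: bool = True) -> float:
        """Signed rate, by default production > 0 (uptake negative)."""
        val = self.q.get(species, 0.0)
        sign = 1.0 if self.roles.get(species) == "production" else -1.0
        return val * (sign if production_positive else -sign)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"species": sp, "q_mmol_gDCW_h": val,
                 "role": self.roles.get(sp, "production")}
                for sp, val in self.q.items()]
        df = pd.DataFrame(rows)
        df.attrs["mu_per_day"] = self.mu
        return df


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def infer_outflow(inlet: GasStream, outlet_fractions: dict[str, float]) -> float:
    """Outlet flow (mL/min) from the argon balance F_out = F_in y_Ar,in / y_Ar,out."""
    y_in = inlet.fraction("Ar")
    if y_in <= 0:
        raise OffgasError("inert-balance inversion requires Ar in the feed")
    y_out = float(outlet_fractions.get("Ar", 0.0))
    if y_out <= 0:
        raise OffgasError("inert species absent from off-gas")
    return inlet.flow * y_in / y_out


def specific_gas_rate(inlet: GasStream, outlet: GasStream, species: str,
                      biomass: float, volume: float,
                      molar_volume: float = MOLAR_VOLUME_STP
                      ) -> tuple[float, str]:
    """Specific uptake/production rate of one species, mmol/gDCW/h.

    q = |F_in y_in - F_out y_out| * 60 / (molar_volume * volume * biomass);
    labelled "uptake" when inflow exceeds outflow, "production" otherwise.
    """
    if biomass <= 0:
        raise OffgasError("biomass must be positive")
    if volume <= 0:
        raise OffgasError("working volume must be positive")
    n_in = inlet.molar_flow(species, molar_volume)
    n_out = outlet.molar_flow(species, molar_volume)
    q = abs(n_in - n_out) * 60.0 / (volume * biomass)
    role = "uptake" if n_in > n_out else "production"
    return q, role


def ethanol_stripping_rate(outlet: GasStream, biomass: float, volume: float,
                           molar_volume: float = MOLAR_VOLUME_STP) -> float:
    """Specific rate of ethanol leaving with the off-gas, mmol/gDCW/h.

    Volatile ethanol stripped into the gas stream bypasses the broth HPLC
    measurement; this flux is added to the liquid-phase ethanol production
    rate before carbon balancing.
    """
    inlet = GasStream(flow=outlet.flow, fractions={})  # y_in = 0 by definition
    q, _ = specific_gas_rate(inlet, outlet, "ethanol", biomass, volume,
                             molar_volume)
    return q


def steady_state_window(trace: pd.DataFrame, window: float,
                        cv_threshold: float = 0.02
                        ) -> tuple[dict[str, float], bool]:
    """Time-average the final ``window`` hours of a trace and judge stability.

    ``trace`` is long-form with columns time_h, species, mole_fraction.
    Stability requires the per-species coefficient of variation within the
    window to be <= ``cv_threshold`` (species with near-zero mean are
    ignored). The default window in the pipeline is four reactor residence
    times — the midpoint of the 3-5 working volumes typically required for
    a chemostat steady state.
    """
    if trace.empty:
        raise OffgasError("empty off-gas trace")
    t_end = trace["time_h"].max()
    t_start = t_end - window
    if trace["time_h"].min() > t_start + 1e-9:
        raise OffgasError("trace shorter than the averaging window")
    recent = trace[trace["time_h"] >= t_start - 1e-9]
    means: dict[str, float] = {}
    stable = True
    for sp, grp in recent.groupby("species"):
        vals = grp["mole_fraction"].to_numpy(float)
        m = float(vals.mean())
        means[sp] = m
        if m > 1e-9 and vals.std(ddof=0) / m > cv_threshold:
            stable = False
    return means, stable


def rates_from_trace(trace: pd.DataFrame, inlet: GasStream, mu: float,
                     biomass: float, volume: float,
                     window: float | None = None, cv_threshold: float = 0.02,
                     molar_volume: float = MOLAR_VOLUME_STP) -> RatePanel:
    """Invert a full off-gas trace into a :class:`RatePanel`.

    Averages the trailing window (default: the whole trace), infers the
    outlet flow from the Ar balance and computes specific rates for every
    measured species except Ar. Ethanol in the off-gas is reported as the
    stripped production rate under the key "ethanol_stripped".
    """
    if window is None:
        window = float(trace["time_h"].max() - trace["time_h"].min())
    means, _stable = steady_state_window(trace, window, cv_threshold)
    total = sum(means.values())
    if total <= 0:
        raise OffgasError("off-gas composition sums to zero")
    means = {sp: y / total for sp, y in means.items()}  # MS scan normalisation
    f_out = infer_outflow(inlet, means)
    outlet = GasStream(flow=f_out, fractions=means)
    q: dict[str, float] = {}
    roles: dict[str, str] = {}
    for sp in SPECIES:
        if sp == "Ar":
            continue
        if sp == "ethanol":
            q["ethanol_stripped"] = ethanol_stripping_rate(
                outlet, biomass, volume, molar_volume)
            roles["ethanol_stripped"] = "production"
            continue
        rate, role = specific_gas_rate(inlet, outlet, sp, biomass, volume,
                                       molar_volume)
        q[sp] = rate
        roles[sp] = role
    return RatePanel(mu=mu, q=q, roles=roles, biomass=biomass,
                     working_volume=volume)


def condition_summary(panels: list[RatePanel]) -> pd.DataFrame:
    """Mean +/- SD of specific rates across bioreplicate panels."""
    if not panels:
        raise OffgasError("no rate panels to summarise")
    rows = []
    species = sorted({sp for p in panels for sp in p.q})
    for sp in species:
        vals = np.array([p.q.get(sp, 0.0) for p in panels])
        rows.append({"species": sp, "mean": vals.mean(),
                     "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     "n": len(vals),
                     "role": panels[0].roles.get(sp, "production")})
    return pd.DataFrame(rows)
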