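"""Forward simulation of steady-state gas-fermentation chemostat datasets.

Every downstream stage of the pipeline (off-gas inversion, carbon
balancing, flux estimation, differential expression) is exercised against
data generated here with known ground truth. The generator emulates the
structure of a 2-gas x 3-dilution-rate chemostat study of
*C. autoethanogenum*: CO (60% CO / 40% Ar) and syngas
(50% CO / 20% H2 / 20% CO2 / 10% Ar) feeds at dilution rates ~1.0, ~2.0 and
~2.8 1/day with 3-6 bioreplicates per condition (23 reactors in total),
plus negative-binomial RNA-seq counts whose log-mean expression is linear
in the growth rate for a planted set of "slope" genes.

Physiology presets keep the study's specific CO/H2 uptake rates, growth
rates, acetate/ethanol ratios and 2,3-BDO carbon fractions, and derive the
remaining product rates from exact C-mol and degree-of-reduction closure,
so that noise-free datasets invert to their generating parameters to
numerical precision and close carbon balances at 100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bioprocess import OD_TO_DCW, HOURS_PER_DAY
from .fluxmodel import BiomassComposition, CoreModel
from .fluxmodel import build_core_model as _build_core_model
from .offgas import MOLAR_VOLUME_STP, SPECIES, GasStream

__all__ = [
    "TruePhysiology",
    "ConditionGrid",
    "SyntheticDataset",
    "DEGConfig",
    "physiology_from_targets",
    "physiology_for_maintenance",
    "default_grid",
    "default_physiologies",
    "simulate_offgas",
    "simulate_broth_and_od",
    "simulate_counts",
    "simulate_annotations",
    "simulate_dataset",
    "write_dataset",
]


class SimulationError(ValueError):
    pass


class InfeasiblePhysiologyError(SimulationError):
    """Gas consumption exceeds supply or a derived rate is negative."""


# --------------------------------------------------------------------------
# physiology
# --------------------------------------------------------------------------

@dataclass
class TruePhysiology:
    """Ground-truth steady-state physiology for one condition.

    Rates are positive magnitudes (uptake for CO/H2, production for CO2),
    mmol/gDCW/h; ``product_carbon_fractions`` give the C-mol split of total
    substrate carbon over {acetate, ethanol, 2,3-BDO, biomass, CO2} and sum
    to 1 exactly.
    """

    mu: float                  # 1/day
    q_CO: float
    q_H2: float
    q_CO2: float
    product_carbon_fractions: dict[str, float]
    maintenance_atp: float     # mmol ATP/gDCW/h (model-derived truth)
    biomass_conc: float        # gDCW/L

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise SimulationError("mu must be positive")
        for name in ("q_CO", "q_H2", "q_CO2"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        s = sum(self.product_carbon_fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise SimulationError(
                f"product carbon fractions sum to {s}, expected 1")

    # product rates implied by the carbon fractions
    @property
    def carbon_uptake(self) -> float:
        """Total substrate carbon uptake, mmol C/gDCW/h."""
        return self.q_CO  # cysteine uptake is zero in the generator

    def product_rate(self, species: str) -> float:
        carbons = {"acetate": 2, "ethanol": 2, "2,3-BDO": 4, "CO2": 1}
        f = self.product_carbon_fractions[species]
        return f * self.carbon_uptake / carbons[species]

    @property
    def q_acetate(self) -> float:
        return self.product_rate("acetate")

    @property
    def q_ethanol(self) -> float:
        return self.product_rate("ethanol")

    @property
    def q_bdo(self) -> float:
        return self.product_rate("2,3-BDO")


def physiology_from_targets(mu: float, q_co: float, q_h2: float,
                            ace_etoh_ratio: float,
                            bdo_carbon_fraction: float,
                            biomass_conc: float,
                            biomass: BiomassComposition | None = None,
                            model: CoreModel | None = None,
                            compute_maintenance: bool = True
                            ) -> TruePhysiology:
    """Derive a balance-closed physiology from target rates and ratios.

    Given mu, the gas uptake rates, the molar acetate/ethanol ratio and the
    2,3-BDO C-mol fraction, the acetate/ethanol/CO2 rates are solved from
    exact carbon and degree-of-reduction closure. The maintenance ATP truth
    is then computed on the core flux model by constraint-based flux
    estimation (maximal ATP dissipation at the derived exchange rates).
    """
    bm = biomass or BiomassComposition()
    e_biomass = 8.0 * bm.acetyl_coa + 10.0 * bm.pyruvate + 2.0 * bm.nadph
    b_c = bm.carbon_mmol * mu / HOURS_PER_DAY        # mmol C/gDCW/h
    b_e = e_biomass * mu / HOURS_PER_DAY             # me-/gDCW/h
    c_up = q_co
    q_b = bdo_carbon_fraction * c_up / 4.0
    # electron closure: 2 q_CO + 2 q_H2 = 8 q_ace + 12 q_etoh + 22 q_bdo + b_e
    q_e = (2.0 * q_co + 2.0 * q_h2 - b_e - 22.0 * q_b) / (
        8.0 * ace_etoh_ratio + 12.0)
    q_a = ace_etoh_ratio * q_e
    # carbon closure fixes CO2
    q_co2 = c_up - b_c - 2.0 * q_a - 2.0 * q_e - 4.0 * q_b
    if min(q_e, q_a, q_co2) < 0:
        raise InfeasiblePhysiologyError(
            "targets imply a negative product rate; reduce the biomass or "
            "by-product demand relative to the electron supply")
    fractions = {
        "acetate": 2.0 * q_a / c_up,
        "ethanol": 2.0 * q_e / c_up,
        "2,3-BDO": 4.0 * q_b / c_up,
        "biomass": b_c / c_up,
        "CO2": q_co2 / c_up,
    }
    # exact unit sum (fix rounding in the last entry)
    fractions["CO2"] += 1.0 - sum(fractions.values())
    maintenance = 0.0
    if compute_maintenance:
        mdl = model or _build_core_model(bm)
        sol = mdl.estimate_fluxes(
            {"co": q_co, "h2": q_h2, "co2": q_co2, "acetate": q_a,
             "ethanol": q_e, "btd": q_b}, mu=mu, tolerance=0.0)
        maintenance = sol.maintenance_atp
    return TruePhysiology(mu=mu, q_CO=q_co, q_H2=q_h2, q_CO2=q_co2,
                          product_carbon_fractions=fractions,
                          maintenance_atp=maintenance,
                          biomass_conc=biomass_conc)


def physiology_for_maintenance(target_maintenance: float, mu: float,
                               h2_to_co: float = 0.0,
                               ace_etoh_ratio: float = 1.0,
                               bdo_carbon_fraction: float = 0.01,
                               biomass_conc: float = 1.6,
                               biomass: BiomassComposition | None = None
                               ) -> TruePhysiology:
    """Calibrate the CO uptake so the model-derived maintenance ATP hits a target.

    The maintenance flux grows monotonically with substrate supply at fixed
    mu, so a scalar root-find on q_CO suffices.
    """
    bm = biomass or BiomassComposition()
    model = _build_core_model(bm)

    def residual(q_co: float) -> float:
        phys = physiology_from_targets(
            mu, q_co, h2_to_co * q_co, ace_etoh_ratio, bdo_carbon_fraction,
            biomass_conc, bm, model)
        return phys.maintenance_atp - target_maintenance

    from .fluxmodel import InfeasibleError

    lo = 2.0
    while True:
        try:
            if residual(lo) < 0:
                break
        except (InfeasiblePhysiologyError, InfeasibleError):
            pass  # q_CO too small to support mu at all: keep growing
        lo *= 1.5
        if lo > 500:
            raise SimulationError("cannot bracket the maintenance target")
    hi = lo
    while residual(hi) < 0:
        hi *= 1.5
        if hi > 2000:
            raise SimulationError("maintenance target unreachable")
    q_co = brentq(residual, lo, hi, xtol=1e-10, rtol=1e-12)
    return physiology_from_targets(mu, q_co, h2_to_co * q_co, ace_etoh_ratio,
                                   bdo_carbon_fraction, biomass_conc, bm,
                                   model)


# --------------------------------------------------------------------------
# condition grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionGrid:
    """Design of one chemostat condition (one gas x dilution-rate cell)."""

    gas: str                     # "CO" | "syngas"
    feed_fractions: Mapping[str, float]
    flow_in: float               # mL/min
    agitation: float             # RPM, metadata only
    dilution: float              # 1/day
    n_replicates: int
    seed: int = 0

    def __post_init__(self) -> None:
        s = sum(self.feed_fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise SimulationError(f"feed fractions sum to {s}, expected 1")

    @property
    def condition_id(self) -> str:
        return f"{self.gas}_D{self.dilution:.2f}"

    def inlet(self) -> GasStream:
        return GasStream(flow=self.flow_in, fractions=dict(self.feed_fractions))


CO_FEED = {"CO": 0.60, "Ar": 0.40}
SYNGAS_FEED = {"CO": 0.50, "H2": 0.20, "CO2": 0.20, "Ar": 0.10}

#: per-condition design: (gas, feed, flow, agitation, D, n_replicates)
_GRID_ROWS = [
    ("CO", CO_FEED, 50.0, 690.0, 1.02, 4),
    ("CO", CO_FEED, 72.0, 815.0, 2.03, 3),
    ("CO", CO_FEED, 72.0, 1175.0, 2.79, 3),
    ("syngas", SYNGAS_FEED, 50.0, 675.0, 1.01, 6),
    ("syngas", SYNGAS_FEED, 72.0, 800.0, 2.01, 3),
    ("syngas", SYNGAS_FEED, 72.0, 1160.0, 2.79, 4),
]

#: physiology targets per condition:
#: (q_CO, q_H2, acetate/ethanol molar ratio, 2,3-BDO C-mol fraction, gDCW/L)
_PHYS_TARGETS = {
    ("CO", 1.02): (32.0, 0.0, 1.5, 0.004, 1.58),
    ("CO", 2.03): (50.0, 0.0, 1.2, 0.004, 1.65),
    ("CO", 2.79): (70.0, 0.0, 0.9, 0.005, 1.65),
    ("syngas", 1.01): (25.0, 7.0, 1.5, 0.015, 1.59),
    ("syngas", 2.01): (50.0, 21.0, 0.9, 0.025, 1.57),
    ("syngas", 2.79): (73.0, 21.0, 0.6, 0.036, 1.43),
}


def default_grid(seed: int = 0) -> list[ConditionGrid]:
    """The 23-reactor, 2-gas x 3-dilution-rate default design."""
    return [ConditionGrid(gas, feed, flow, agit, d, n, seed)
            for gas, feed, flow, agit, d, n in _GRID_ROWS]


def default_physiologies(biomass: BiomassComposition | None = None,
                         compute_maintenance: bool = True
                         ) -> dict[str, TruePhysiology]:
    """Balance-closed physiologies calibrated to the default grid."""
    bm = biomass or BiomassComposition()
    model = _build_core_model(bm) if compute_maintenance else None
    out = {}
    for (gas, d), (q_co, q_h2, ratio, f_bdo, x) in _PHYS_TARGETS.items():
        phys = physiology_from_targets(d, q_co, q_h2, ratio, f_bdo, x, bm,
                                       model,
                                       compute_maintenance=compute_maintenance)
        out[f"{gas}_D{d:.2f}"] = phys
    return out


# --------------------------------------------------------------------------
# off-gas / broth simulation
# --------------------------------------------------------------------------

def simulate_offgas(phys: TruePhysiology, grid_row: ConditionGrid,
                    noise_sd: float = 0.0, n_timepoints: int = 25,
                    seed: int = 0, stripped_fraction: float = 0.05,
                    duration_h: float = 12.0, replicate_id: str = "r1",
                    volume: float = 0.75,
                    molar_volume: float = MOLAR_VOLUME_STP
                    ) -> tuple[pd.DataFrame, float]:
    """Forward-simulate the off-gas trace of one replicate.

    Species molar outflows are inflow - consumption + production; argon is
    conserved exactly and mole fractions are renormalised over the measured
    species. ``stripped_fraction`` of the total produced ethanol leaves
    with the off-gas. Multiplicative Gaussian noise of relative SD
    ``noise_sd`` is applied per timepoint when positive. Returns the
    long-form trace and the true (noise-free) outlet flow in mL/min.
    """
    if grid_row.flow_in <= 0:
        raise SimulationError("feed flow must be positive")
    if grid_row.feed_fractions.get("Ar", 0.0) <= 0:
        raise SimulationError("feed must contain argon for inert balancing")
    X, V = phys.biomass_conc, volume
    to_vol = X * V / 60.0 * molar_volume   # mmol/gDCW/h -> mL/min

    net = {sp: 0.0 for sp in SPECIES}
    net["CO"] = -phys.q_CO * to_vol
    net["H2"] = -phys.q_H2 * to_vol
    net["CO2"] = phys.q_CO2 * to_vol
    net["ethanol"] = stripped_fraction * phys.q_ethanol * to_vol

    out_flows = {}
    for sp in SPECIES:
        flow = grid_row.flow_in * grid_row.feed_fractions.get(sp, 0.0) + net[sp]
        if flow < -1e-9:
            raise InfeasiblePhysiologyError(
                f"computed outflow of {sp} is negative: consumption exceeds "
                "supply for this feed")
        out_flows[sp] = max(flow, 0.0)
    f_out = sum(out_flows.values())
    fractions = {sp: out_flows[sp] / f_out for sp in SPECIES}

    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, duration_h, n_timepoints)
    records = []
    for t in times:
        for sp in SPECIES:
            y = fractions[sp]
            if noise_sd > 0:
                y *= 1.0 + noise_sd * rng.standard_normal()
            records.append({"time_h": t, "species": sp,
                            "mole_fraction": max(y, 0.0),
                            "replicate_id": replicate_id})
    return pd.DataFrame.from_records(records), f_out


def simulate_broth_and_od(phys: TruePhysiology, dilution: float,
                          noise_sd: float = 0.0, seed: int = 0,
                          stripped_fraction: float = 0.05,
                          n_timepoints: int = 5,
                          replicate_id: str = "r1"
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Steady-state broth concentrations (mM) and OD600 series.

    Noise-free concentrations satisfy q_i = (D/24) c_i / X exactly; the
    broth ethanol excludes the stripped fraction, which only appears in the
    off-gas. OD600 is biomass / 0.23.
    """
    if dilution <= 0:
        raise SimulationError("dilution rate must be positive")
    X = phys.biomass_conc
    d_h = dilution / HOURS_PER_DAY
    conc = {
        "acetate": phys.q_acetate * X / d_h,
        "ethanol": (1.0 - stripped_fraction) * phys.q_ethanol * X / d_h,
        "2,3-BDO": phys.q_bdo * X / d_h,
    }
    rng = np.random.default_rng(seed)
    rows = []
    for sp, c in conc.items():
        obs = c * (1.0 + noise_sd * rng.standard_normal()) if noise_sd > 0 else c
        rows.append({"replicate_id": replicate_id, "species": sp,
                     "conc_mM": max(obs, 0.0)})
    broth = pd.DataFrame(rows)
    od_true = X / OD_TO_DCW
    od_vals = np.full(n_timepoints, od_true)
    if noise_sd > 0:
        od_vals = od_vals * (1.0 + noise_sd * rng.standard_normal(n_timepoints))
    od = pd.DataFrame({"replicate_id": replicate_id,
                       "timepoint": np.arange(n_timepoints),
                       "od600": od_vals})
    return broth, od


# --------------------------------------------------------------------------
# RNA-seq counts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGConfig:
    """Planted differential-expression structure for the count simulator.

    ``slope`` is the planted |log2 expression change| per unit mu (1/day);
    with the default grid's mu span of ~1.8/day the planted genes move
    ~3.5-fold end to end, comfortably past the 1.5-fold calling threshold.
    ``dispersion`` is the negative-binomial dispersion (var = m + disp m^2);
    the small default mirrors the tight bioreplicate agreement of chemostat
    cultures. Half of the planted genes get identical slopes on both gases
    (the "tight-control" truth); the other half differ two-fold between
    gases.
    """

    n_up: int = 100
    n_down: int = 100
    slope: float = 1.0
    dispersion: float = 0.005
    library_size_range: tuple[float, float] = (5.6e6, 9.3e6)
    tight_fraction: float = 0.5
    gas_slope_factor: float = 0.5
    baseline_log2cpm: tuple[float, float] = (5.0, 8.0)
    flat_log2cpm: tuple[float, float] = (2.0, 9.0)


def _design_from_grid(grid: list[ConditionGrid]) -> pd.DataFrame:
    rows = []
    for g in grid:
        for r in range(g.n_replicates):
            rows.append({"sample_id": f"{g.condition_id}_r{r + 1}",
                         "gas": g.gas, "mu": g.dilution,
                         "replicate": r + 1,
                         "condition_id": g.condition_id})
    return pd.DataFrame(rows)


def simulate_counts(n_genes: int, design: pd.DataFrame,
                    deg_config: DEGConfig | None = None, seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial RNA-seq counts with mu-dependent planted signal.

    ``design`` needs columns sample_id, gas and mu; at least two mu levels
    and two replicates per condition are required for testability. Returns
    (counts genes x samples, gene lengths in bp, truth table).
    """
    cfg = deg_config or DEGConfig()
    if n_genes < 100:
        raise SimulationError("n_genes must be at least 100")
    if design["mu"].nunique() < 2:
        raise SimulationError("count simulation needs at least two mu levels")
    if (design.groupby(["gas", "mu"]).size() < 2).any():
        raise SimulationError("need >= 2 replicates per condition")
    n_planted = cfg.n_up + cfg.n_down
    if n_planted > n_genes:
        raise SimulationError("more planted DEGs than genes")

    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    gases = sorted(design["gas"].unique())
    mu_ref = float(design["mu"].mean())

    classes = np.array(["flat"] * n_genes, dtype=object)
    classes[:cfg.n_up] = "up"
    classes[cfg.n_up:n_planted] = "down"
    # per-gas slopes; a tight subset has identical slopes on both gases
    slopes = {gas: np.zeros(n_genes) for gas in gases}
    is_tight = np.zeros(n_genes, dtype=bool)
    for i in range(n_planted):
        s = cfg.slope if classes[i] == "up" else -cfg.slope
        tight = rng.random() < cfg.tight_fraction
        is_tight[i] = tight
        for j, gas in enumerate(gases):
            factor = 1.0 if (tight or j == 0) else cfg.gas_slope_factor
            slopes[gas][i] = s * factor

    base = rng.uniform(*cfg.flat_log2cpm, size=n_genes)
    base[:n_planted] = rng.uniform(*cfg.baseline_log2cpm, size=n_planted)
    lengths = pd.Series(rng.integers(300, 3001, size=n_genes), index=genes,
                        name="length_bp")
    lib_sizes = rng.uniform(*cfg.library_size_range, size=len(design))

    counts = np.zeros((n_genes, len(design)), dtype=np.int64)
    for s_idx, row in enumerate(design.itertuples()):
        log2cpm = base + slopes[row.gas] * (row.mu - mu_ref)
        frac = 2.0 ** log2cpm
        # normalise so the expected total equals the sampled sequencing depth
        mean = frac / frac.sum() * lib_sizes[s_idx]
        if cfg.dispersion > 0:
            n_param = 1.0 / cfg.dispersion
            p_param = n_param / (n_param + mean)
            counts[:, s_idx] = rng.negative_binomial(n_param, p_param)
        else:
            counts[:, s_idx] = rng.poisson(mean)

    counts_df = pd.DataFrame(counts, index=genes,
                             columns=design["sample_id"].tolist())
    truth = pd.DataFrame({"gene_id": genes, "class": classes,
                          "is_tight": is_tight,
                          "base_log2cpm": base})
    for gas in gases:
        truth[f"slope_{gas}"] = slopes[gas]
    return counts_df, lengths, truth.set_index("gene_id")


def simulate_annotations(truth: pd.DataFrame, seed: int = 0,
                         n_terms: int = 50, n_enriched: int = 5,
                         enriched_purity: float = 0.8
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mock GO and COG annotation tables with a known enriched subset.

    ``n_enriched`` GO terms draw ``enriched_purity`` of their members from
    the planted slope genes, giving the enrichment stage a known positive
    answer; the remaining terms sample uniformly (sizes 5-200 genes).
    """
    rng = np.random.default_rng(seed)
    genes = truth.index.to_numpy()
    slope_genes = truth.index[truth["class"] != "flat"].to_numpy()
    go_rows = []
    for t in range(n_terms):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(5, 201))
        if t < n_enriched and len(slope_genes) > 0:
            n_sig = min(int(round(size * enriched_purity)), len(slope_genes))
            members = list(rng.choice(slope_genes, size=n_sig, replace=False))
            others = rng.choice(genes, size=min(size - n_sig, len(genes)),
                                replace=False)
            members.extend(others)
        else:
            members = rng.choice(genes, size=min(size, len(genes)),
                                 replace=False)
        go_rows.extend({"gene_id": g, "term_id": term}
                       for g in dict.fromkeys(members))
    go = pd.DataFrame(go_rows)
    cog_letters = list("CDEFGHIJKLMNOPQRSTUV")
    annotated = rng.random(len(genes)) < 0.6
    cog = pd.DataFrame({
        "gene_id": genes[annotated],
        "cog_letter": rng.choice(cog_letters, size=int(annotated.sum()))})
    return go, cog


# --------------------------------------------------------------------------
# full dataset
# --------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A complete in-memory synthetic study with ground truth."""

    grid: list[ConditionGrid]
    physiologies: dict[str, TruePhysiology]
    offgas_traces: pd.DataFrame      # long form + condition/replicate ids
    broth: pd.DataFrame
    od: pd.DataFrame
    counts: pd.DataFrame
    gene_lengths: pd.Series
    go_annotations: pd.DataFrame
    cog_annotations: pd.DataFrame
    design: pd.DataFrame
    truth_genes: pd.DataFrame
    stripped_fraction: float
    noise_sd: float
    seed: int
    working_volume: float = 0.75

    def condition(self, condition_id: str) -> ConditionGrid:
        for g in self.grid:
            if g.condition_id == condition_id:
                return g
        raise KeyError(condition_id)


def simulate_dataset(grid: list[ConditionGrid] | None = None,
                     physiologies: Mapping[str, TruePhysiology] | None = None,
                     noise_sd: float = 0.02, stripped_fraction: float = 0.05,
                     n_genes: int = 2000, deg_config: DEGConfig | None = None,
                     seed: int = 0, n_timepoints: int = 25,
                     working_volume: float = 0.75,
                     compute_maintenance: bool = True) -> SyntheticDataset:
    """Simulate the full study: off-gas, broth, OD, counts, annotations."""
    grid = grid if grid is not None else default_grid(seed)
    if physiologies is None:
        physiologies = default_physiologies(
            compute_maintenance=compute_maintenance)
    root = np.random.default_rng(seed)

    traces, broths, ods = [], [], []
    for g in grid:
        phys = physiologies[g.condition_id]
        for r in range(g.n_replicates):
            rid = f"r{r + 1}"
            sub = int(root.integers(0, 2**31 - 1))
            trace, _ = simulate_offgas(
                phys, g, noise_sd=noise_sd, n_timepoints=n_timepoints,
                seed=sub, stripped_fraction=stripped_fraction,
                replicate_id=rid, volume=working_volume)
            trace["condition_id"] = g.condition_id
            traces.append(trace)
            broth, od = simulate_broth_and_od(
                phys, g.dilution, noise_sd=noise_sd, seed=sub + 1,
                stripped_fraction=stripped_fraction, replicate_id=rid)
            broth["condition_id"] = g.condition_id
            od["condition_id"] = g.condition_id
            broths.append(broth)
            ods.append(od)

    design = _design_from_grid(grid)
    counts, lengths, truth = simulate_counts(
        n_genes, design, deg_config, seed=int(root.integers(0, 2**31 - 1)))
    go, cog = simulate_annotations(truth,
                                   seed=int(root.integers(0, 2**31 - 1)))

    return SyntheticDataset(
        grid=grid, physiologies=dict(physiologies),
        offgas_traces=pd.concat(traces, ignore_index=True),
        broth=pd.concat(broths, ignore_index=True),
        od=pd.concat(ods, ignore_index=True),
        counts=counts, gene_lengths=lengths,
        go_annotations=go, cog_annotations=cog, design=design,
        truth_genes=truth, stripped_fraction=stripped_fraction,
        noise_sd=noise_sd, seed=seed, working_volume=working_volume)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset as plain-text tables; returns the path map."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(df: pd.DataFrame, name: str, sep: str, index=False):
        p = out / name
        df.to_csv(p, sep=sep, index=index)
        paths[name] = str(p)

    save(ds.offgas_traces, "offgas_traces.csv", ",")
    save(ds.broth, "broth.tsv", "\t")
    save(ds.od, "od.tsv", "\t")
    save(ds.counts, "counts.tsv", "\t", index=True)
    save(ds.gene_lengths.to_frame(), "gene_lengths.tsv", "\t", index=True)
    save(ds.go_annotations, "go_annotations.tsv", "\t")
    save(ds.cog_annotations, "cog_annotations.tsv", "\t")
    save(ds.design, "design.tsv", "\t")
    grid_df = pd.DataFrame([
        {"condition_id": g.condition_id, "gas": g.gas,
         "flow_in_mL_min": g.flow_in, "agitation_rpm": g.agitation,
         "dilution_per_day": g.dilution, "n_replicates": g.n_replicates,
         **{f"feed_{sp}": y for sp, y in g.feed_fractions.items()}}
        for g in ds.grid])
    save(grid_df, "conditions.tsv", "\t")

    truth = {
        "seed": ds.seed,
        "noise_sd": ds.noise_sd,
        "stripped_fraction": ds.stripped_fraction,
        "working_volume_L": ds.working_volume,
        "physiology": {cid: asdict(p) for cid, p in ds.physiologies.items()},
        "n_true_up": int((ds.truth_genes["class"] == "up").sum()),
        "n_true_down": int((ds.truth_genes["class"] == "down").sum()),
    }
    p = out / "truth.json"
    with open(p, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    paths["truth.json"] = str(p)
    ds.truth_genes.to_csv(out / "truth_genes.tsv", sep="\t")
    paths["truth_genes.tsv"] = str(out / "truth_genes.tsv")
    return paths
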