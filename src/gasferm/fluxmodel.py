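"""Core acetogen stoichiometric model and flux balance analysis (FBA).

This module implements a compact (~30 reaction) representation of the central
carbon and redox metabolism of carboxydotrophic acetogens such as
*Clostridium autoethanogenum*: CO oxidation by carbon monoxide dehydrogenase
(CODH), the methyl branch of the Wood-Ljungdahl pathway (CO2 -> formate ->
methyl-THF), acetyl-CoA synthase (ACS), acetate/ethanol/2,3-butanediol
formation, and the chemiosmotic energy machinery (electron-bifurcating
MTHFR, Rnf, ATP synthase, Nfn transhydrogenase, HytA-E hydrogenase).

Three structural choices define the energy metabolism here:

a) methylene-THF reductase is NADH-dependent and electron-bifurcating,
   reducing ferredoxin;
b) the membrane-bound Rnf complex translocates 2 H+ per reduced ferredoxin
   oxidised;
c) the ATP synthase operates at 4 H+ per ATP.

The model is solved by linear programming (scipy's HiGHS) with the two FBA
procedures used for steady-state chemostat data: flux estimation under
measured exchange-rate constraints with maximisation of ATP dissipation, and
growth-phenotype prediction under substrate-uptake constraints with
maximisation of biomass yield (optionally with H2-utilisation coupling
constraints).

The statsmodels-style surface is ``CoreModel`` (the model object) whose
solver methods return a ``FluxSolution`` results object with a ``summary()``
table and derived redox/energy statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "BiomassComposition",
    "CoreModel",
    "FluxSolution",
    "FluxModelError",
    "InfeasibleError",
    "build_core_model",
    "theoretical_co2_loss",
]

#: hours per day, used to convert dilution rates (1/day) into fluxes (1/h)
HOURS_PER_DAY = 24.0

_INF = 1e6  # finite stand-in for an unbounded flux; keeps HiGHS happy


class FluxModelError(ValueError):
    """Raised for malformed models or invalid solver inputs."""


class InfeasibleError(FluxModelError):
    """Raised when an LP required to be solvable has no feasible point."""


@dataclass(frozen=True)
class Metabolite:
    """A model species with the bookkeeping needed for balance checks.

    ``electrons`` is the degree of reduction (available electrons per mole)
    relative to CO2/H2O/NH3/H2S; carrier pairs (NAD(P)H, ferredoxin) differ
    by exactly the electrons they carry.
    """

    id: str
    name: str = ""
    carbon_atoms: int = 0
    electrons: float = 0.0
    compartment: str = "cytosol"


@dataclass
class Reaction:
    """A stoichiometric reaction; negative coefficients are consumed."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = _INF
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def equation(self, arrow: str = "-->") -> str:
        lhs = " + ".join(
            f"{-c:g} {m}" if c != -1 else m
            for m, c in sorted(self.stoichiometry.items())
            if c < 0
        )
        rhs = " + ".join(
            f"{c:g} {m}" if c != 1 else m
            for m, c in sorted(self.stoichiometry.items())
            if c > 0
        )
        if self.reversible:
            arrow = "<=>"
        return f"{lhs} {arrow} {rhs}"


@dataclass(frozen=True)
class BiomassComposition:
    """Precursor and cofactor demand of the biomass pseudo-reaction.

    Units are mmol per gDCW. ``atp`` follows the Bauchop-Elsden yield for
    anaerobes (Y_ATP ~ 10.5 g biomass per mol ATP, i.e. ~95 mmol ATP/gDCW);
    the carbon content implied by the precursor draw (2 C per acetyl-CoA,
    3 C per pyruvate) is exposed as ``carbon_mmol`` and matches the
    0.0417 C-mol/gDCW default used in the C-mol balance.
    """

    acetyl_coa: float = 15.0
    pyruvate: float = 3.9
    atp: float = 95.0
    nadph: float = 12.0

    @property
    def carbon_mmol(self) -> float:
        """mmol carbon fixed per gDCW of biomass."""
        return 2.0 * self.acetyl_coa + 3.0 * self.pyruvate

    @property
    def carbon_cmol(self) -> float:
        """C-mol per gDCW."""
        return self.carbon_mmol / 1000.0


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

def _metabolites() -> dict[str, Metabolite]:
    mets = [
        Metabolite("co_c", "carbon monoxide", 1, 2),
        Metabolite("co2_c", "carbon dioxide", 1, 0),
        Metabolite("h2_c", "hydrogen", 0, 2),
        Metabolite("for_c", "formate", 1, 2),
        Metabolite("thf_c", "tetrahydrofolate", 0, 0),
        Metabolite("mlthf_c", "methylene-THF", 1, 4),
        Metabolite("methf_c", "methyl-THF", 1, 6),
        Metabolite("coa_c", "coenzyme A", 0, 0),
        Metabolite("accoa_c", "acetyl-CoA", 2, 8),
        Metabolite("acp_c", "acetyl phosphate", 2, 8),
        Metabolite("ac_c", "acetate", 2, 8),
        Metabolite("acald_c", "acetaldehyde", 2, 10),
        Metabolite("etoh_c", "ethanol", 2, 12),
        Metabolite("pyr_c", "pyruvate", 3, 10),
        Metabolite("alac_c", "2-acetolactate", 5, 20),
        Metabolite("actn_c", "acetoin", 4, 20),
        Metabolite("btd_c", "2,3-butanediol", 4, 22),
        Metabolite("cys_c", "cysteine", 3, 10),
        Metabolite("nh3_c", "ammonia", 0, 0),
        Metabolite("h2s_c", "hydrogen sulfide", 0, 0),
        Metabolite("atp_c", "ATP", 0, 0),
        Metabolite("adp_c", "ADP", 0, 0),
        Metabolite("pi_c", "phosphate", 0, 0),
        Metabolite("nad_c", "NAD+", 0, 0),
        Metabolite("nadh_c", "NADH", 0, 2),
        Metabolite("nadp_c", "NADP+", 0, 0),
        Metabolite("nadph_c", "NADPH", 0, 2),
        Metabolite("fdox_c", "oxidised ferredoxin", 0, 0),
        Metabolite("fdred_c", "reduced ferredoxin", 0, 2),
        Metabolite("h_c", "proton (cytosol)", 0, 0),
        Metabolite("h_e", "proton (outside)", 0, 0, "extracellular"),
        Metabolite("h2o_c", "water", 0, 0),
        # biomass carries non-integer carbon; exempt from balance checks
        Metabolite("biomass_c", "biomass", 0, 0),
    ]
    return {m.id: m for m in mets}


#: exchangeable species and default (lb, ub) of the exchange flux
#: (positive flux = secretion, negative = uptake)
_EXCHANGES = {
    "co_c": (0.0, 0.0),
    "h2_c": (0.0, 0.0),
    "co2_c": (0.0, _INF),
    "ac_c": (0.0, _INF),
    "etoh_c": (0.0, _INF),
    "btd_c": (0.0, _INF),
    "cys_c": (0.0, 0.0),
    "nh3_c": (0.0, _INF),
    "h2s_c": (0.0, _INF),
    "h2o_c": (-_INF, _INF),
    "h_c": (-_INF, _INF),
    "biomass_c": (0.0, _INF),
}


def build_core_model(biomass: BiomassComposition | None = None) -> "CoreModel":
    """Construct the core Wood-Ljungdahl network.

    Every internal (non-exchange, non-biomass) reaction is validated for
    elemental carbon balance and degree-of-reduction (electron) closure; an
    imbalance raises :class:`FluxModelError` naming the reaction.
    """
    bm = biomass or BiomassComposition()
    mets = _metabolites()

    rxns: list[Reaction] = []

    def rxn(rid, stoich, lb=0.0, ub=_INF, name=""):
        rxns.append(Reaction(rid, dict(stoich), lb, ub, name))

    # --- carbonyl branch / CO oxidation
    rxn("CODH", {"co_c": -1, "h2o_c": -1, "fdox_c": -1,
                 "co2_c": 1, "fdred_c": 1, "h_c": 2},
        name="carbon monoxide dehydrogenase")
    # --- CO2 reduction to formate
    # both CO2->formate routes irreversible toward formate: allowing the
    # reverse lets an FdhA/formate-H2-lyase/Hyt triangle turn NADPH into
    # Fd_red and pump protons for free (a thermodynamically impossible loop)
    rxn("rxn00103_c0", {"co2_c": -1, "nadph_c": -1, "h_c": -1,
                        "for_c": 1, "nadp_c": 1},
        name="formate dehydrogenase (NADPH, FdhA)")
    rxn("rxn08518_c0", {"co2_c": -1, "h2_c": -1, "for_c": 1, "h_c": 1},
        name="formate-H2 lyase (HytA-E/FdhA)")
    rxn("leq000001", {"h2_c": -2, "fdox_c": -1, "nadp_c": -1,
                      "fdred_c": 1, "nadph_c": 1, "h_c": 1},
        name="electron-bifurcating hydrogenase (HytA-E)")
    # --- methyl branch
    rxn("FTS", {"for_c": -1, "thf_c": -1, "atp_c": -1, "nadph_c": -1,
                "h_c": -1, "mlthf_c": 1, "adp_c": 1, "pi_c": 1,
                "nadp_c": 1, "h2o_c": 1},
        name="formate->methylene-THF (lumped synthetase/cyclohydrolase/dehydrogenase)")
    rxn("MTHFR", {"mlthf_c": -1, "nadh_c": -2, "fdox_c": -1,
                  "methf_c": 1, "nad_c": 2, "fdred_c": 1},
        name="methylene-THF reductase (bifurcating, NADH)")
    rxn("ACS", {"methf_c": -1, "co_c": -1, "coa_c": -1,
                "accoa_c": 1, "thf_c": 1},
        name="acetyl-CoA synthase")
    # --- acetate and ethanol
    rxn("PTA", {"accoa_c": -1, "pi_c": -1, "acp_c": 1, "coa_c": 1},
        lb=-_INF, name="phosphotransacetylase")
    rxn("ACK", {"acp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
        lb=-_INF, name="acetate kinase")
    rxn("AOR", {"ac_c": -1, "fdred_c": -1, "h_c": -2,
                "acald_c": 1, "fdox_c": 1, "h2o_c": 1},
        name="aldehyde:ferredoxin oxidoreductase")
    rxn("ADH", {"acald_c": -1, "nadph_c": -1, "h_c": -1,
                "etoh_c": 1, "nadp_c": 1},
        name="alcohol dehydrogenase (NADPH)")
    rxn("ADHE", {"accoa_c": -1, "nadh_c": -2, "h_c": -2,
                 "etoh_c": 1, "coa_c": 1, "nad_c": 2},
        name="bifunctional aldehyde/alcohol dehydrogenase")
    # --- pyruvate and 2,3-butanediol
    rxn("PFOR", {"accoa_c": -1, "co2_c": -1, "fdred_c": -1, "h_c": -1,
                 "pyr_c": 1, "coa_c": 1, "fdox_c": 1, "h2o_c": 1},
        name="pyruvate:ferredoxin oxidoreductase")
    rxn("ALS", {"pyr_c": -2, "h_c": -1, "alac_c": 1, "co2_c": 1},
        name="acetolactate synthase")
    rxn("ALDC", {"alac_c": -1, "h_c": -1, "actn_c": 1, "co2_c": 1},
        name="acetolactate decarboxylase")
    rxn("BDH", {"actn_c": -1, "nadph_c": -1, "h_c": -1,
                "btd_c": 1, "nadp_c": 1},
        name="2,3-butanediol dehydrogenase (NADPH)")
    # --- energy and redox machinery
    rxn("RNF", {"fdred_c": -1, "nad_c": -1, "h_c": -2,
                "fdox_c": 1, "nadh_c": 1, "h_e": 2},
        lb=-_INF, name="Rnf complex (2 H+/Fd_red)")
    rxn("ATPS", {"adp_c": -1, "pi_c": -1, "h_e": -4,
                 "atp_c": 1, "h2o_c": 1, "h_c": 3},
        lb=-_INF, name="ATP synthase (4 H+/ATP)")
    rxn("NFN", {"fdred_c": -1, "nadh_c": -1, "nadp_c": -2, "h_c": -1,
                "fdox_c": 1, "nad_c": 1, "nadph_c": 2},
        lb=-_INF, name="Nfn transhydrogenase")
    rxn("ATPM", {"atp_c": -1, "h2o_c": -1,
                 "adp_c": 1, "pi_c": 1, "h_c": 1},
        name="ATP maintenance (non-growth dissipation)")
    # --- amino-acid substrate
    rxn("CYSDEG", {"cys_c": -1, "h2o_c": -1,
                   "pyr_c": 1, "nh3_c": 1, "h2s_c": 1},
        name="cysteine desulfhydration to pyruvate")
    # --- biomass pseudo-reaction (exempt from balance checks)
    rxn("BIOMASS", {"accoa_c": -bm.acetyl_coa, "pyr_c": -bm.pyruvate,
                    "atp_c": -bm.atp, "nadph_c": -bm.nadph,
                    "h2o_c": -bm.atp,
                    "biomass_c": 1, "coa_c": bm.acetyl_coa,
                    "adp_c": bm.atp, "pi_c": bm.atp,
                    "nadp_c": bm.nadph, "h_c": bm.atp},
        name="biomass synthesis (1 gDCW per unit flux)")
    # --- exchanges
    for met, (lb, ub) in _EXCHANGES.items():
        rxns.append(Reaction(f"EX_{met[:-2]}", {met: -1}, lb, ub,
                             name=f"{mets[met].name} exchange"))

    model = CoreModel(metabolites=mets, reactions=rxns, biomass=bm)
    model.validate()
    return model


# --------------------------------------------------------------------------
# model object
# --------------------------------------------------------------------------

@dataclass
class CoreModel:
    """Stoichiometric model with named central-metabolism fluxes.

    The stoichiometric matrix ``S`` (metabolites x reactions) is built
    lazily; reaction bounds live on the :class:`Reaction` objects and are
    copied, not mutated, by the solver methods.
    """

    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    biomass: BiomassComposition = field(default_factory=BiomassComposition)

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}

    # -- introspection -----------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise FluxModelError(f"unknown reaction id: {rid!r}") from None

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[self._met_index[met], j] = coef
        return S

    def is_exchange(self, rid: str) -> bool:
        return rid.startswith("EX_")

    def validate(self, atol: float = 1e-9) -> None:
        """Check elemental carbon and electron closure of internal reactions."""
        for r in self.reactions:
            if self.is_exchange(r.id) or r.id == "BIOMASS":
                continue
            carbon = sum(c * self.metabolites[m].carbon_atoms
                         for m, c in r.stoichiometry.items())
            electrons = sum(c * self.metabolites[m].electrons
                            for m, c in r.stoichiometry.items())
            if abs(carbon) > atol:
                raise FluxModelError(
                    f"reaction {r.id} is carbon-imbalanced ({carbon:+g} C)")
            if abs(electrons) > atol:
                raise FluxModelError(
                    f"reaction {r.id} is electron-imbalanced ({electrons:+g} e-)")

    # -- LP machinery ------------------------------------------------------
    def _solve(self, objective: Mapping[str, float], sense: str = "max",
               bound_overrides: Mapping[str, tuple[float, float]] | None = None,
               extra_constraints: Sequence[tuple[Mapping[str, float], str, float]] = (),
               pfba: bool = True) -> "FluxSolution":
        n = len(self.reactions)
        idx = self._rxn_index
        S = self.stoichiometric_matrix
        bounds = [(r.lower_bound, r.upper_bound) for r in self.reactions]
        if bound_overrides:
            for rid, (lb, ub) in bound_overrides.items():
                bounds[idx[rid]] = (lb, ub)
        c = np.zeros(n)
        for rid, w in objective.items():
            c[idx[rid]] += w
        sign = -1.0 if sense == "max" else 1.0

        A_ub, b_ub, A_eq, b_eq = [], [], [S], [np.zeros(S.shape[0])]
        for coeffs, op, rhs in extra_constraints:
            row = np.zeros(n)
            for rid, w in coeffs.items():
                row[idx[rid]] += w
            if op == "eq":
                A_eq.append(row[None, :]); b_eq.append([rhs])
            elif op == "le":
                A_ub.append(row); b_ub.append(rhs)
            elif op == "ge":
                A_ub.append(-row); b_ub.append(-rhs)
            else:
                raise FluxModelError(f"unknown constraint sense {op!r}")
        A_eq_m = np.vstack(A_eq)
        b_eq_v = np.concatenate([np.atleast_1d(b) for b in b_eq])
        A_ub_m = np.vstack(A_ub) if A_ub else None
        b_ub_v = np.array(b_ub) if A_ub else None

        res = linprog(sign * c, A_ub=A_ub_m, b_ub=b_ub_v,
                      A_eq=A_eq_m, b_eq=b_eq_v, bounds=bounds,
                      method="highs")
        if res.status == 2:
            return FluxSolution(model=self, fluxes=None, objective_value=np.nan,
                                status="infeasible")
        if res.status == 3:
            return FluxSolution(model=self, fluxes=None, objective_value=np.nan,
                                status="unbounded")
        if not res.success:  # pragma: no cover - solver hiccup
            return FluxSolution(model=self, fluxes=None, objective_value=np.nan,
                                status=f"solver-failure({res.status})")
        z = float(c @ res.x)
        v = res.x
        if pfba:
            v2 = self._minimise_total_flux(c, z, bounds, A_ub_m, b_ub_v,
                                           A_eq_m, b_eq_v)
            if v2 is not None:
                v = v2
        return FluxSolution(
            model=self,
            fluxes=pd.Series(v, index=self.reaction_ids, name="flux"),
            objective_value=z, status="optimal")

    def _minimise_total_flux(self, c, z, bounds, A_ub, b_ub, A_eq, b_eq):
        """Secondary LP: among optima, minimise sum |v| for reproducibility."""
        n = len(bounds)
        # variables [v, t]; t >= v, t >= -v
        obj = np.concatenate([np.zeros(n), np.ones(n)])
        I = np.eye(n)
        rows_ub = [np.hstack([I, -I]), np.hstack([-I, -I])]
        rhs_ub = [np.zeros(n), np.zeros(n)]
        if A_ub is not None:
            rows_ub.append(np.hstack([A_ub, np.zeros((A_ub.shape[0], n))]))
            rhs_ub.append(b_ub)
        A_ub2 = np.vstack(rows_ub)
        b_ub2 = np.concatenate(rhs_ub)
        A_eq2 = np.vstack([np.hstack([A_eq, np.zeros((A_eq.shape[0], n))]),
                           np.concatenate([c, np.zeros(n)])[None, :]])
        b_eq2 = np.concatenate([b_eq, [z]])
        bounds2 = list(bounds) + [(0, None)] * n
        res = linprog(obj, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_eq2, b_eq=b_eq2,
                      bounds=bounds2, method="highs")
        return res.x[:n] if res.success else None

    # -- public FBA surface ------------------------------------------------
    def fba(self, objective: str | Mapping[str, float], sense: str = "max",
            extra_constraints: Sequence[tuple[Mapping[str, float], str, float]] = (),
            bound_overrides: Mapping[str, tuple[float, float]] | None = None,
            pfba: bool = True) -> "FluxSolution":
        """Solve max/min c'v subject to S v = 0, bounds and extra constraints.

        ``objective`` is a reaction id or a {reaction: weight} mapping.
        Returns a :class:`FluxSolution`; infeasible/unbounded problems are
        reported through its ``status``, never silently.
        """
        if isinstance(objective, str):
            objective = {objective: 1.0}
        for rid in objective:
            self.reaction(rid)  # raises on unknown id
        return self._solve(objective, sense, bound_overrides,
                           extra_constraints, pfba)

    def estimate_fluxes(self, measured: Mapping[str, float], mu: float,
                        tolerance: float = 0.02,
                        q_cysteine: float = 0.0) -> "FluxSolution":
        """Estimate intracellular fluxes from measured steady-state rates.

        Exchange fluxes are fixed to the measured specific rates (positive
        magnitudes, mmol/gDCW/h; uptake for CO/H2/cysteine, production for
        CO2, acetate, ethanol, 2,3-BDO) within a relative ``tolerance``
        band, the biomass flux is fixed to mu (1/day, converted to 1/h),
        and the ATP-maintenance flux is maximised — the flux-estimation
        objective for energy-limited acetogens.
        """
        key_to_ex = {"co": ("EX_co", -1), "h2": ("EX_h2", -1),
                     "co2": ("EX_co2", 1), "acetate": ("EX_ac", 1),
                     "ethanol": ("EX_etoh", 1), "btd": ("EX_btd", 1),
                     "bdo": ("EX_btd", 1)}
        overrides: dict[str, tuple[float, float]] = {}
        for key, q in measured.items():
            try:
                ex, s = key_to_ex[key.lower()]
            except KeyError:
                raise FluxModelError(f"unknown measured species {key!r}") from None
            if q < 0:
                raise FluxModelError(f"measured rate for {key} must be a "
                                     "positive magnitude")
            lo, hi = q * (1 - tolerance), q * (1 + tolerance)
            overrides[ex] = (s * hi, s * lo) if s < 0 else (s * lo, s * hi)
        v_bio = mu / HOURS_PER_DAY
        overrides["EX_biomass"] = (v_bio * (1 - tolerance),
                                   v_bio * (1 + tolerance))
        overrides["EX_cys"] = (-q_cysteine * (1 + tolerance),
                               -q_cysteine * (1 - tolerance))
        sol = self._solve({"ATPM": 1.0}, "max", overrides)
        if sol.status != "optimal":
            raise InfeasibleError(
                f"flux estimation {sol.status} at tolerance {tolerance:g}; "
                "the measured rates may not close the carbon/electron "
                "balance — check the C-mol recovery of this condition or "
                "widen the tolerance band")
        return sol

    def predict_phenotype(self, q_co: float, q_h2: float = 0.0,
                          q_cysteine: float = 0.0,
                          maintenance_atp: float = 0.0,
                          coupling: bool = False) -> "FluxSolution":
        """Predict the optimal growth phenotype from substrate uptakes.

        Substrate uptake rates (positive magnitudes) and the ATP
        dissipation (maintenance) flux are fixed and biomass yield is
        maximised. With ``coupling`` on, H2 utilisation is tied to redox
        generation: NADPH-consuming CO2 reduction by FdhA (rxn00103_c0) is
        zeroed and the formate-H2-lyase flux (rxn08518_c0) is fixed at
        r x the bifurcating-hydrogenase flux (leq000001), with
        r = q_H2/q_CO of the experiment.
        """
        if min(q_co, q_h2, q_cysteine) < 0:
            raise FluxModelError("uptake rates must be non-negative")
        # uptakes are capacities (<=): under the coupling constraints a
        # hard-fixed H2 uptake can strand electrons with no sink
        overrides = {"EX_co": (-q_co, 0.0), "EX_h2": (-q_h2, 0.0),
                     "EX_cys": (-q_cysteine, 0.0),
                     "ATPM": (maintenance_atp, maintenance_atp)}
        extra = []
        if coupling:
            overrides["rxn00103_c0"] = (0.0, 0.0)
            r = q_h2 / q_co if q_co > 0 else 0.0
            # bifurcating-hydrogenase flux tied to the formate-H2-lyase flux
            # at the experiment's H2:CO availability; the opposite
            # orientation (lyase = r x hydrogenase) over-reduces the network
            # (> 4 electrons of H2 per methyl group) and admits only the
            # zero flux vector
            extra.append(({"leq000001": 1.0, "rxn08518_c0": -r}, "eq", 0.0))
        return self._solve({"EX_biomass": 1.0}, "max", overrides, extra)

    # -- serialisation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Reaction table (id, name, equation, bounds) for TSV export."""
        return pd.DataFrame(
            {"reaction_id": [r.id for r in self.reactions],
             "name": [r.name for r in self.reactions],
             "equation": [r.equation() for r in self.reactions],
             "lower_bound": [r.lower_bound for r in self.reactions],
             "upper_bound": [r.upper_bound for r in self.reactions]})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# results object
# --------------------------------------------------------------------------

@dataclass
class FluxSolution:
    """FBA results: flux vector, status and derived bioenergetic statistics."""

    model: CoreModel
    fluxes: pd.Series | None
    objective_value: float
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rid: str) -> float:
        if self.fluxes is None:
            raise FluxModelError(f"no flux vector: solution is {self.status}")
        return float(self.fluxes[rid])

    # -- invariants --------------------------------------------------------
    def steady_state_residual(self) -> float:
        """max |S v| over metabolites; ~0 for any optimal solution."""
        S = self.model.stoichiometric_matrix
        return float(np.abs(S @ self.fluxes.to_numpy()).max())

    def exchange_electron_residual(self) -> float:
        """Degree-of-reduction closure over exchange + biomass fluxes."""
        bm = self.model.biomass
        total = 0.0
        for r in self.model.reactions:
            if not self.model.is_exchange(r.id):
                continue
            met = next(iter(r.stoichiometry))
            total += -self[r.id] * self.model.metabolites[met].electrons
        # electrons retained in biomass: precursor + NADPH draw
        e_biomass = (8.0 * bm.acetyl_coa + 10.0 * bm.pyruvate
                     + 2.0 * bm.nadph)
        total -= self["BIOMASS"] * e_biomass
        return float(total)

    # -- derived statistics ------------------------------------------------
    @property
    def maintenance_atp(self) -> float:
        """Non-growth ATP dissipation flux, mmol/gDCW/h."""
        return self["ATPM"]

    def _positive_production(self, met: str, exclude=("BIOMASS",)) -> float:
        """Sum of positive production fluxes of ``met`` over internal reactions."""
        total = 0.0
        for r in self.model.reactions:
            if self.model.is_exchange(r.id) or r.id in exclude:
                continue
            coef = r.stoichiometry.get(met, 0.0)
            rate = coef * self[r.id]
            if rate > 0:
                total += rate
        return total

    @property
    def fdred_from_co_fraction(self) -> float | None:
        """Fraction of reduced ferredoxin generated by CO oxidation (CODH)."""
        total = self._positive_production("fdred_c")
        if total <= 0:
            return None
        codh = max(self["CODH"], 0.0)
        return codh / total

    @property
    def atpase_to_ack_ratio(self) -> float | None:
        """Ratio of the ATP-producing fluxes of ATP synthase and acetate kinase."""
        ack = self["ACK"]
        if abs(ack) < 1e-12:
            return None
        return self["ATPS"] / ack

    @property
    def maintenance_fraction_of_total_atp(self) -> float | None:
        """Maintenance dissipation as a fraction of total ATP production."""
        total = self._positive_production("atp_c")
        if total <= 0:
            return None
        return self["ATPM"] / total

    @property
    def wlp_flux(self) -> float:
        """Flux through the Wood-Ljungdahl pathway (acetyl-CoA synthase)."""
        return self["ACS"]

    @property
    def mu(self) -> float:
        """Predicted/fitted specific growth rate, 1/day."""
        return self["EX_biomass"] * HOURS_PER_DAY

    def derived_statistics(self) -> dict[str, float | None]:
        return {
            "maintenance_atp": self.maintenance_atp,
            "fdred_from_co_fraction": self.fdred_from_co_fraction,
            "atpase_to_ack_ratio": self.atpase_to_ack_ratio,
            "maintenance_fraction_of_total_atp":
                self.maintenance_fraction_of_total_atp,
            "wlp_flux": self.wlp_flux,
        }

    def summary(self) -> str:
        lines = [
            "Core acetogen flux balance solution",
            "=" * 40,
            f"status:           {self.status}",
            f"objective value:  {self.objective_value:.6g}",
        ]
        if self.optimal:
            lines += [
                f"steady-state residual: {self.steady_state_residual():.2e}",
                f"mu (1/day):       {self.mu:.4g}",
                "",
                "derived statistics",
                "-" * 40,
            ]
            for k, v in self.derived_statistics().items():
                lines.append(f"{k:35s} "
                             + ("undefined" if v is None else f"{v:.4g}"))
            lines += ["", "fluxes (mmol/gDCW/h)", "-" * 40]
            for rid, v in self.fluxes.items():
                if abs(v) > 1e-9:
                    lines.append(f"{rid:15s} {v:12.4f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "status": self.status,
            "objective_value": self.objective_value,
            "fluxes": (None if self.fluxes is None
                       else self.fluxes.round(10).to_dict()),
            "derived": (self.derived_statistics() if self.optimal else None),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# --------------------------------------------------------------------------
# theoretical yields
# --------------------------------------------------------------------------

def theoretical_co2_loss(model: CoreModel | None = None,
                         feed_ratio: float = np.inf,
                         sole_product: str = "ethanol") -> float:
    """Fraction of substrate carbon emitted as CO2 for a sole product.

    ``feed_ratio`` is the CO:H2 molar uptake ratio (``inf`` = pure CO). The
    model is constrained to zero biomass and all products except the chosen
    one; the product export is maximised at fixed CO uptake and the CO2
    export per CO consumed is returned (0..1).
    """
    model = model or build_core_model()
    product_ex = {"ethanol": "EX_etoh", "acetate": "EX_ac",
                  "btd": "EX_btd", "2,3-bdo": "EX_btd"}
    try:
        target = product_ex[sole_product.lower()]
    except KeyError:
        raise FluxModelError(f"unknown sole product {sole_product!r}") from None
    q_co = 1.0
    q_h2 = 0.0 if np.isinf(feed_ratio) else q_co / feed_ratio
    overrides = {"EX_co": (-q_co, -q_co), "EX_h2": (-q_h2, -q_h2),
                 "EX_biomass": (0.0, 0.0), "EX_cys": (0.0, 0.0)}
    for ex in ("EX_ac", "EX_etoh", "EX_btd"):
        if ex != target:
            overrides[ex] = (0.0, 0.0)
    sol = model.fba(target, "max", bound_overrides=overrides)
    if not sol.optimal:
        raise InfeasibleError(
            f"{sole_product} unreachable at CO:H2 = {feed_ratio}: {sol.status}")
    return sol["EX_co2"] / q_co
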