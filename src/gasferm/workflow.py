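"""End-to-end orchestration: simulate -> rates -> balance -> FBA -> DE -> report.

Stages run in dependency order and write their outputs before dependents
run; a failing stage aborts the run with its name. The whole pipeline is
driven by one :class:`~gasferm.config.RunConfig` and a single seed, and the
report payload is deterministic for a given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioprocess, offgas, synthetic, transcriptomics as tx
from .config import RunConfig
from .fluxmodel import build_core_model
from .synthetic import DEGConfig, SyntheticDataset

__all__ = ["run_pipeline", "analyse_dataset", "Report"]

log = logging.getLogger("gasferm")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


class Report(dict):
    """JSON-serialisable pipeline report with provenance."""

    def to_json(self, path=None) -> str:
        text = json.dumps(self, indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = ["# gasferm pipeline report", ""]
        prov = self.get("provenance", {})
        lines += [f"- seed: {prov.get('seed')}",
                  f"- config hash: {prov.get('config_hash')}", ""]
        lines.append("## Specific rates (condition means, mmol/gDCW/h)")
        for cid, cond in self.get("conditions", {}).items():
            lines.append(f"### {cid}")
            for sp, stats_ in cond.get("rates", {}).items():
                lines.append(f"- q_{sp}: {stats_['mean']:.2f} "
                             f"± {stats_['sd']:.2f}")
            cb = cond.get("carbon_balance", {})
            if cb:
                lines.append(f"- carbon recovery: {cb['recovery']:.1f}%")
            fx = cond.get("flux", {})
            if fx:
                lines.append(f"- maintenance ATP: "
                             f"{fx['maintenance_atp']:.2f} mmol/gDCW/h")
            lines.append("")
        deg = self.get("transcriptome", {})
        if deg:
            lines.append("## Transcriptome")
            lines.append(f"- DEG universe: {deg.get('n_deg_total')}")
            lines.append(f"- expression clusters: {deg.get('n_clusters')}")
            lines.append(f"- tight-control genes: {deg.get('n_tight_control')}")
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# --------------------------------------------------------------------------
# analysis of an in-memory dataset (re-used by tests and the CLI)
# --------------------------------------------------------------------------

def replicate_rate_panels(ds: SyntheticDataset, config: RunConfig
                          ) -> dict[str, list[offgas.RatePanel]]:
    """Invert every replicate's off-gas trace + broth into a rate panel."""
    panels: dict[str, list[offgas.RatePanel]] = {}
    for g in ds.grid:
        inlet = g.inlet()
        cond_panels = []
        for rid, trace in ds.offgas_traces[
                ds.offgas_traces["condition_id"] == g.condition_id].groupby(
                    "replicate_id"):
            od_mean = ds.od[(ds.od["condition_id"] == g.condition_id)
                            & (ds.od["replicate_id"] == rid)]["od600"].mean()
            biomass = bioprocess.biomass_from_od(od_mean, config.od_to_dcw)
            residence_h = 24.0 / g.dilution  # one working volume, in hours
            window = min(config.window_residence_times * residence_h,
                         float(trace["time_h"].max() - trace["time_h"].min()))
            panel = offgas.rates_from_trace(
                trace, inlet, mu=g.dilution, biomass=biomass,
                volume=ds.working_volume, window=window,
                cv_threshold=config.cv_threshold,
                molar_volume=config.molar_volume_mL_mmol)
            # liquid-phase rates from broth concentrations
            broth = ds.broth[(ds.broth["condition_id"] == g.condition_id)
                             & (ds.broth["replicate_id"] == rid)]
            conc = dict(zip(broth["species"], broth["conc_mM"]))
            stripped = panel.q.get("ethanol_stripped", 0.0)
            panel.q["acetate"] = bioprocess.liquid_specific_rate(
                conc.get("acetate", 0.0), g.dilution, biomass)
            panel.q["ethanol"] = bioprocess.liquid_specific_rate(
                conc.get("ethanol", 0.0), g.dilution, biomass,
                stripped_q=stripped)
            panel.q["2,3-BDO"] = bioprocess.liquid_specific_rate(
                conc.get("2,3-BDO", 0.0), g.dilution, biomass)
            for sp in ("acetate", "ethanol", "2,3-BDO"):
                panel.roles[sp] = "production"
            cond_panels.append(panel)
        panels[g.condition_id] = cond_panels
    return panels


def condition_balances(panels: dict[str, list[offgas.RatePanel]],
                       ds: SyntheticDataset, config: RunConfig) -> dict:
    carbon = bioprocess.SpeciesCarbon(
        biomass_cmol=config.biomass_cmol_per_gdcw)
    out = {}
    for g in ds.grid:
        per_rep = []
        for panel in panels[g.condition_id]:
            products = {"acetate": panel.q.get("acetate", 0.0),
                        "ethanol": panel.q.get("ethanol", 0.0),
                        "2,3-BDO": panel.q.get("2,3-BDO", 0.0),
                        "CO2": panel.q.get("CO2", 0.0)}
            substrates = {"CO": panel.q.get("CO", 0.0)}
            if config.q_cysteine > 0:
                substrates["cysteine"] = config.q_cysteine
            per_rep.append(bioprocess.carbon_balance(
                products, panel.mu, substrates, carbon))
        recs = np.array([cb.recovery for cb in per_rep])
        mean_fractions = {
            sp: float(np.mean([cb.fractions[sp] for cb in per_rep]))
            for sp in per_rep[0].fractions}
        out[g.condition_id] = {
            "recovery": float(recs.mean()),
            "recovery_sd": float(recs.std(ddof=1)) if len(recs) > 1 else 0.0,
            "fractions": mean_fractions,
        }
    return out


def analyse_dataset(ds: SyntheticDataset, config: RunConfig | None = None
                    ) -> Report:
    """Run the full analysis on an in-memory dataset; returns the report."""
    config = config or RunConfig()
    report = Report(conditions={}, transcriptome={},
                    provenance={"seed": ds.seed,
                                "config_hash": _config_hash(config)})
    # --- rates
    try:
        panels = replicate_rate_panels(ds, config)
    except Exception as exc:
        raise StageError("rates", exc) from exc
    for cid, cond_panels in panels.items():
        summary = offgas.condition_summary(cond_panels)
        report["conditions"][cid] = {
            "n_replicates": len(cond_panels),
            "mu": cond_panels[0].mu,
            "rates": {row.species: {"mean": row.mean, "sd": row.sd}
                      for row in summary.itertuples()},
        }
    # --- carbon balance
    try:
        balances = condition_balances(panels, ds, config)
    except Exception as exc:
        raise StageError("balance", exc) from exc
    for cid, cb in balances.items():
        report["conditions"][cid]["carbon_balance"] = cb
    # --- flux estimation
    try:
        model = build_core_model()
        for cid, cond_panels in panels.items():
            mean_q = {sp: float(np.mean([p.q.get(sp, 0.0)
                                         for p in cond_panels]))
                      for sp in cond_panels[0].q}
            sol = model.estimate_fluxes(
                {"co": mean_q.get("CO", 0.0), "h2": mean_q.get("H2", 0.0),
                 "co2": mean_q.get("CO2", 0.0),
                 "acetate": mean_q.get("acetate", 0.0),
                 "ethanol": mean_q.get("ethanol", 0.0),
                 "btd": mean_q.get("2,3-BDO", 0.0)},
                mu=cond_panels[0].mu, tolerance=config.flux_tolerance)
            report["conditions"][cid]["flux"] = {
                k: v for k, v in sol.derived_statistics().items()}
    except Exception as exc:
        raise StageError("fba", exc) from exc
    # --- transcriptomics
    try:
        matrix = tx.ExpressionMatrix(ds.counts, ds.gene_lengths,
                                     ds.design.set_index("sample_id"))
        expressed = tx.filter_expressed(matrix.rpkm(),
                                        config.rpkm_threshold,
                                        config.rpkm_min_samples)
        deg_tables = {}
        for gas in sorted(ds.design["gas"].unique()):
            mus = ds.design.loc[ds.design["gas"] == gas, "mu"]
            for hi, lo in tx.within_gas_comparisons(mus):
                deg_tables[(gas, hi, lo)] = tx.deg_call(
                    matrix, (gas, hi, lo), config.fc_threshold,
                    config.q_threshold, expressed)
        universe = set()
        for tab in deg_tables.values():
            universe |= set(tab.index[tab["is_deg"]])
        report["transcriptome"]["n_deg_total"] = len(universe)
        report["transcriptome"]["n_deg_per_comparison"] = {
            f"{gas}:{hi:g}_vs_{lo:g}": int(tab["is_deg"].sum())
            for (gas, hi, lo), tab in deg_tables.items()}
        n_clusters = 0
        if len(universe) >= 2:
            log2 = matrix.log2cpm().loc[sorted(universe)]
            # condition-mean profiles across mu x gas
            cols = {}
            for (gas, mu), grp in ds.design.groupby(["gas", "mu"]):
                cols[f"{gas}_{mu:g}"] = log2[grp["sample_id"]].mean(axis=1)
            profiles = pd.DataFrame(cols)
            _labels, n_clusters, _ = tx.cluster_profiles(profiles)
        report["transcriptome"]["n_clusters"] = int(n_clusters)
        tight = tx.tight_control_selection(matrix, deg_tables,
                                           alpha=config.slope_alpha)
        n_tight = int(tight["retained"].sum()) if len(tight) else 0
        report["transcriptome"]["n_tight_control"] = n_tight
        if len(universe) >= 1:
            enr = tx.enrichment(universe & set(expressed),
                                ds.go_annotations.rename(
                                    columns={"term_id": "term_id"}),
                                set(expressed))
            report["transcriptome"]["n_enriched_go_terms"] = int(
                enr["significant"].sum()) if len(enr) else 0
    except Exception as exc:
        raise StageError("degs", exc) from exc
    return report


# --------------------------------------------------------------------------
# file-based pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir=None) -> Report:
    """Simulate a dataset, analyse it end-to-end and write all outputs."""
    config.validate()
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("stage simulate: seed=%d", config.seed)
    try:
        deg_cfg = DEGConfig(n_up=config.deg_n_up, n_down=config.deg_n_down,
                            slope=config.deg_slope,
                            dispersion=config.deg_dispersion)
        ds = synthetic.simulate_dataset(
            noise_sd=config.noise_sd,
            stripped_fraction=config.stripped_fraction,
            n_genes=config.n_genes, deg_config=deg_cfg, seed=config.seed,
            n_timepoints=config.n_timepoints,
            working_volume=config.working_volume_L)
        synthetic.write_dataset(ds, out / "simulated")
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    report = analyse_dataset(ds, config)
    report.to_json(out / "report.json")
    (out / "report.md").write_text(report.to_markdown())
    log.info("pipeline complete: %s", out)
    return report
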