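"""Desk-scale orchestration of the whole quantitative study.

``run_study`` generates (or loads) per-layer synapse populations for a
set of cases and stacks, applies the unbiased counting frame, estimates
raw and corrected synaptic densities, runs the CSR spatial tests, the
proportion reports and the statistical battery, and emits a per-layer
summary table in the style of the study's main table, plus CSV/JSON/
markdown artifacts.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import counting, spatial_stats, stats_engine, synthgen
from .stereology import ShrinkageFactors, round_half_up

log = logging.getLogger("synaptostats3d")

LAYER_ORDER = list(synthgen.LAYERS)


def percentage(part: float, total: float, decimals: int = 2) -> float:
    """Share of ``part`` in ``total`` as a percent, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * part / total, decimals)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Study configuration; defaults reproduce the desk-scale design.

    Five cases with three stacks per case and per layer mirror the
    study's sampling plan; the stack footprint matches the acquisition
    field of view (10.24 x 7.68 um in-plane) with a 5 um depth.
    Shrinkage factors default to identity so that recovered quantities
    can be compared directly with the generator's ground truth; pass
    measured factors to exercise the correction arithmetic.
    """

    seed: int = 0
    n_cases: int = 5
    stacks_per_case: int = 3
    stack_extent_nm: tuple[float, float, float] = (10240.0, 7680.0, 5000.0)
    cf_margin_nm: float = 400.0
    factors: ShrinkageFactors | None = None
    artifact_fraction_range: tuple[float, float] = (0.0, 0.0)
    profiles: dict[str, synthgen.LayerProfile] | None = None
    spatial_functions: tuple[str, ...] = ("G", "K")
    spatial_n_sim: int = 99
    spatial_stacks_per_layer: int = 1
    layer_thickness_mm: dict[str, float] = field(default_factory=lambda: {
        "alveus": 0.34, "SO": 0.06, "SP": 1.13, "SR": 0.55, "SLM": 0.62})

    def resolved_profiles(self) -> dict[str, synthgen.LayerProfile]:
        return self.profiles or synthgen.load_layer_profiles()


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def thickness_report(thickness: dict[str, float]) -> pd.DataFrame:
    """Relative contribution of each layer to the total thickness.

    Shares are integer-rounded percentages (report style).
    """
    if any(v <= 0 for v in thickness.values()):
        raise ValueError("layer thicknesses must be positive")
    total = sum(thickness.values())
    rows = [{"layer": k, "thickness": v,
             "share_percent": int(round_half_up(100.0 * v / total, 0))}
            for k, v in thickness.items()]
    return pd.DataFrame(rows)


def proportions_report(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-layer and pooled percentage tables.

    ``target_by_polarity`` covers only synapses with an identified
    postsynaptic target (the unknowns are excluded and the denominators
    reported); ``shape_by_polarity`` covers all records.  Cells with a
    zero denominator carry NA percentages.
    """
    out: dict[str, pd.DataFrame] = {}

    def tidy(df: pd.DataFrame, column: str, categories) -> pd.DataFrame:
        rows = []
        layers = ["all"] + [l for l in LAYER_ORDER if l in set(df["layer"])]
        for layer in layers:
            sub_l = df if layer == "all" else df[df["layer"] == layer]
            for pol in ("all",) + synthgen.POLARITIES:
                sub = sub_l if pol == "all" else sub_l[sub_l["polarity"] == pol]
                denom = len(sub)
                for cat in categories:
                    n = int((sub[column] == cat).sum())
                    rows.append({
                        "layer": layer, "polarity": pol, column: cat,
                        "n": n, "denominator": denom,
                        "percent": percentage(n, denom) if denom else np.nan,
                    })
        return pd.DataFrame(rows)

    identified = records[records["target"] != "unknown"]
    targets = [t for t in synthgen.TARGETS if t != "unknown"]
    out["target_by_polarity"] = tidy(identified, "target", targets)
    out["shape_by_polarity"] = tidy(records, "shape_class", synthgen.SHAPE_CLASSES)

    # axospinous vs axodendritic convenience view
    t = out["target_by_polarity"].copy()
    t["group"] = np.where(t["target"].str.startswith("spine"),
                          "axospinous", "axodendritic")
    grp = (t.groupby(["layer", "polarity", "group"], sort=False)
             .agg(n=("n", "sum"), denominator=("denominator", "first"))
             .reset_index())
    grp["percent"] = [percentage(n, d) if d else np.nan
                      for n, d in zip(grp["n"], grp["denominator"])]
    out["axospinous_share"] = grp
    return out


# ---------------------------------------------------------------------------
# The study driver
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Bundle of everything ``run_study`` computes."""

    layer_summary: pd.DataFrame
    records: pd.DataFrame
    stack_table: pd.DataFrame
    proportions: dict[str, pd.DataFrame]
    spatial: dict[str, dict[str, spatial_stats.SpatialFnResult]]
    stats_table: pd.DataFrame
    fits: pd.DataFrame
    thickness: pd.DataFrame
    config: RunConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.layer_summary.to_csv(out / "layer_summary.csv", index=False)
        self.records.to_csv(out / "synapses.csv", index=False)
        self.stack_table.to_csv(out / "stacks.csv", index=False)
        for name, df in self.proportions.items():
            df.to_csv(out / f"proportions_{name}.csv", index=False)
        self.stats_table.to_csv(out / "statistical_tests.csv", index=False)
        self.fits.to_csv(out / "size_distribution_fits.csv", index=False)
        self.thickness.to_csv(out / "thickness_shares.csv", index=False)
        verdicts = {}
        for layer, fns in self.spatial.items():
            verdicts[layer] = {fn: bool(res.verdict) for fn, res in fns.items()}
            for fn, res in fns.items():
                res.to_frame().to_csv(out / f"spatial_{layer}_{fn}.csv", index=False)
        (out / "spatial_verdicts.json").write_text(json.dumps(verdicts, indent=2))
        (out / "report.md").write_text(self.to_markdown())

    def to_markdown(self) -> str:
        lines = ["# Synthetic CA1 synapse study report", ""]
        lines.append(f"Seed: {self.config.seed}; cases: {self.config.n_cases}; "
                     f"stacks/case/layer: {self.config.stacks_per_case}")
        lines.append("")
        lines.append("## Per-layer summary")
        lines.append(self.layer_summary.to_markdown(index=False))
        lines.append("")
        lines.append("## CSR verdicts")
        for layer, fns in self.spatial.items():
            verdict = ", ".join(f"{fn}: {'within' if r.verdict else 'outside'}"
                                for fn, r in fns.items())
            lines.append(f"- {layer}: {verdict}")
        lines.append("")
        lines.append("## Statistical tests")
        lines.append(self.stats_table.to_markdown(index=False))
        return "\n".join(lines) + "\n"


def _layer_summary_row(layer: str, recs: pd.DataFrame, stacks: pd.DataFrame,
                       factors: ShrinkageFactors | None) -> dict:
    n_as = int((recs["polarity"] == "AS").sum())
    n_ss = int((recs["polarity"] == "SS").sum())
    n_tot = n_as + n_ss
    assert n_as + n_ss == len(recs)
    cf_raw = stacks["cf_volume_um3"].sum()
    cf_corr = stacks["cf_volume_corrected_um3"].sum()
    case = stacks.groupby("case")
    dens = case["n_included"].sum() / case["cf_volume_um3"].sum()
    dens_as = case.apply(lambda s: s["n_as"].sum() / s["cf_volume_um3"].sum(),
                         include_groups=False)
    dens_ss = case.apply(lambda s: s["n_ss"].sum() / s["cf_volume_um3"].sum(),
                         include_groups=False)
    nn_mean = recs["nn_nm"].mean() if "nn_nm" in recs and len(recs) else np.nan
    p = factors.p if factors else 1.0
    p2 = factors.p2 if factors else 1.0
    row = {
        "layer": layer, "n_AS": n_as, "n_SS": n_ss, "n_total": n_tot,
        "pct_AS": percentage(n_as, n_tot) if n_tot else np.nan,
        "pct_SS": percentage(n_ss, n_tot) if n_tot else np.nan,
        "cf_volume_um3": round_half_up(cf_raw, 2),
        "cf_volume_corrected_um3": round_half_up(cf_corr, 2),
        "density_AS_mean": round_half_up(dens_as.mean(), 2),
        "density_AS_sd": round_half_up(dens_as.std(ddof=1), 2),
        "density_SS_mean": round_half_up(dens_ss.mean(), 2),
        "density_SS_sd": round_half_up(dens_ss.std(ddof=1), 2),
        "density_all_mean": round_half_up(dens.mean(), 2),
        "density_all_sd": round_half_up(dens.std(ddof=1), 2),
        "intersynaptic_nm": round_half_up(nn_mean, 2) if np.isfinite(nn_mean) else np.nan,
        "intersynaptic_corrected_nm": (round_half_up(nn_mean / p, 2)
                                       if np.isfinite(nn_mean) else np.nan),
    }
    for pol in synthgen.POLARITIES:
        areas = recs.loc[recs["polarity"] == pol, "sas_area_nm2"]
        mean_a = areas.mean() if len(areas) else np.nan
        row[f"sas_area_{pol}_mean"] = round_half_up(mean_a, 2) if len(areas) else np.nan
        row[f"sas_area_{pol}_corrected_mean"] = (
            round_half_up(mean_a / p2, 2) if len(areas) else np.nan)
    # internal consistency checks (enforced on every report)
    if n_tot:
        assert abs(row["pct_AS"] + row["pct_SS"] - 100.0) <= 0.011
        assert abs((dens_as + dens_ss - dens).abs().max()) < 1e-9
    return row


def run_study(config: RunConfig | None = None, out_dir=None) -> StudyResult:
    """Run the full synthetic study and (optionally) write its bundle."""
    cfg = config or RunConfig()
    profiles = cfg.resolved_profiles()
    master = np.random.default_rng(cfg.seed)
    ex, ey, ez = cfg.stack_extent_nm

    all_records: list[pd.DataFrame] = []
    stack_rows: list[dict] = []
    spatial: dict[str, dict[str, spatial_stats.SpatialFnResult]] = {}

    for layer in [l for l in LAYER_ORDER if l in profiles]:
        profile = profiles[layer]
        log.info("layer %s: generating %d x %d stacks (intensity %.2f/um^3)",
                 layer, cfg.n_cases, cfg.stacks_per_case, profile.intensity)
        layer_patterns = []
        for case in range(cfg.n_cases):
            for stack_i in range(cfg.stacks_per_case):
                af = float(master.uniform(*cfg.artifact_fraction_range))
                geom = synthgen.StackGeometry(ex, ey, ez, artifact_fraction=af)
                seed = int(master.integers(2 ** 31))
                pop = synthgen.generate_population(geom, profile, seed)
                frame = counting.CountingFrame.from_stack(geom, cfg.cf_margin_nm)
                inc, meta = counting.counting_frame_filter(pop, frame, geom)
                inc = inc.copy()
                inc["case"] = case
                inc["stack"] = stack_i
                if len(inc) >= 2:
                    pat = spatial_stats.PointPattern(
                        inc[["cx_nm", "cy_nm", "cz_nm"]].to_numpy() -
                        np.asarray(frame.lo),
                        synthgen.StackGeometry(
                            *(np.asarray(frame.hi) - np.asarray(frame.lo))))
                    inc["nn_nm"] = spatial_stats.nn_distances(pat)
                    layer_patterns.append(pat)
                else:
                    inc["nn_nm"] = np.nan
                dens = counting.synaptic_density(
                    meta["n_included"], frame.volume_um3)
                corr_vol = frame.volume_um3
                if cfg.factors is not None:
                    corr_vol = frame.volume_um3 * (1 - af) / cfg.factors.s_vol
                stack_rows.append({
                    "layer": layer, "case": case, "stack": stack_i,
                    "artifact_fraction": af,
                    "n_generated": len(pop),
                    "n_included": meta["n_included"],
                    "n_as": int((inc["polarity"] == "AS").sum()),
                    "n_ss": int((inc["polarity"] == "SS").sum()),
                    "cf_volume_um3": frame.volume_um3,
                    "cf_volume_corrected_um3": corr_vol,
                    "density_raw": dens.density_per_um3,
                })
                all_records.append(inc)
        # spatial verdicts on the first stack(s) of the layer
        spatial[layer] = {}
        for pat in layer_patterns[:cfg.spatial_stacks_per_layer]:
            for fn in cfg.spatial_functions:
                spatial[layer][fn] = spatial_stats.csr_envelope(
                    pat, function=fn, n_sim=cfg.spatial_n_sim,
                    seed=int(master.integers(2 ** 31)))

    records = (pd.concat(all_records, ignore_index=True)
               if all_records else pd.DataFrame(
                   columns=list(synthgen.SYNAPSE_COLUMNS) + ["case", "stack", "nn_nm"]))
    stack_table = pd.DataFrame(stack_rows)

    summary = pd.DataFrame([
        _layer_summary_row(layer, records[records["layer"] == layer],
                           stack_table[stack_table["layer"] == layer], cfg.factors)
        for layer in [l for l in LAYER_ORDER if l in profiles]])
    if len(summary):
        pooled = _layer_summary_row("all", records, stack_table, cfg.factors)
        summary = pd.concat([summary, pd.DataFrame([pooled])], ignore_index=True)

    proportions = (proportions_report(records) if len(records)
                   else {"target_by_polarity": pd.DataFrame(),
                         "shape_by_polarity": pd.DataFrame(),
                         "axospinous_share": pd.DataFrame()})

    # --- statistical battery -------------------------------------------------
    results: list[stats_engine.TestResult] = []
    ids: list[str] = []
    fit_rows: list[dict] = []
    if len(records):
        layers_present = [l for l in LAYER_ORDER if l in set(records["layer"])]
        cont = pd.DataFrame({
            l: [int(((records["layer"] == l) & (records["polarity"] == p)).sum())
                for p in synthgen.POLARITIES]
            for l in layers_present}, index=list(synthgen.POLARITIES))
        if (cont.to_numpy().sum(axis=0) > 0).all() and len(layers_present) > 1:
            results.append(stats_engine.chi2_contingency(
                cont.to_numpy().T, n_basis="synapses"))
            ids.append("layer_x_polarity_chi2")
        case_dens = stack_table.groupby(["layer", "case"]).apply(
            lambda s: s["n_included"].sum() / s["cf_volume_um3"].sum(),
            include_groups=False)
        groups = {l: case_dens[l].to_numpy() for l in layers_present
                  if len(case_dens[l]) >= 2}
        if len(groups) >= 2:
            anova, _ = stats_engine.anova_tukey(groups, n_basis="subjects")
            results.append(anova)
            ids.append("density_across_layers_anova")
        a_area = records.loc[records["polarity"] == "AS", "sas_area_nm2"]
        s_area = records.loc[records["polarity"] == "SS", "sas_area_nm2"]
        if len(a_area) and len(s_area):
            results.append(stats_engine.ks_two_sample(a_area, s_area,
                                                      n_basis="synapses"))
            ids.append("sas_area_AS_vs_SS_ks")
            case_mean = records.groupby(["polarity", "case"])["sas_area_nm2"].mean()
            results.append(stats_engine.mann_whitney(
                case_mean["AS"].to_numpy(), case_mean["SS"].to_numpy(),
                n_basis="subjects"))
            ids.append("sas_area_AS_vs_SS_mw_case_means")
        for pol, sample in (("AS", a_area), ("SS", s_area)):
            if len(sample) >= 10:
                for fam in ("lognormal", "loglogistic"):
                    fit = stats_engine.fit_size_distribution(sample.to_numpy(), fam)
                    fit_rows.append({"polarity": pol, "family": fam,
                                     **{f"param_{k}": v for k, v in fit.params.items()},
                                     "log_likelihood": fit.log_likelihood,
                                     "ks_distance": fit.ks_distance, "aic": fit.aic})
        by_layer = summary[summary["layer"] != "all"]
        if len(by_layer) >= 3 and by_layer["intersynaptic_nm"].notna().all():
            r2 = stats_engine.r_squared(by_layer["density_all_mean"],
                                        by_layer["intersynaptic_nm"])
            fit_rows.append({"polarity": "all", "family": "density_vs_nn_r2",
                             "param_r2": r2, "log_likelihood": np.nan,
                             "ks_distance": np.nan, "aic": np.nan})

    stats_table = stats_engine.results_table(results, ids)
    fits = pd.DataFrame(fit_rows)
    thickness = thickness_report(cfg.layer_thickness_mm)

    result = StudyResult(layer_summary=summary, records=records,
                         stack_table=stack_table, proportions=proportions,
                         spatial=spatial, stats_table=stats_table, fits=fits,
                         thickness=thickness, config=cfg)
    if out_dir is not None:
        result.write(out_dir)
    return result
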