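"""End-to-end orchestration: simulate -> measure -> compose -> rtf -> stats.

Each stage reads and writes declared TSV/JSON files inside one output
directory, so stages can be re-run independently and a full run with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import measurements as meas
from . import rtf as rtfmod
from . import stats as statsmod
from . import synthetic as syn

log = logging.getLogger("micrortf")

__all__ = ["RunConfig", "run_pipeline", "analyze_dataset", "stage_simulate",
           "stage_measure", "stage_compose", "stage_rtf", "stage_stats"]


def analyze_dataset(
    ds: syn.SyntheticDataset,
    purity: float = 0.90,
    coverage: float = 0.85,
    min_reads: int = 2000,
) -> dict:
    """In-memory analysis of a simulated dataset (no files).

    Runs the same chain as the disk stages — function summaries, depth and
    contaminant filters, monoculture catalog, per-community RTF table — and
    returns the intermediate objects keyed by name.
    """
    asv = ds.asv
    blank_ids = [s for s in asv.sample_ids if asv.meta.loc[s, "blank"]]
    summaries = meas.summarize_all(ds.timeseries, blank_ids=blank_ids)
    filtered = comp.filter_min_depth(asv, min_reads)
    cleaned, contaminants = comp.remove_contaminants(filtered)
    catalog = rtfmod.identify_monocultures(cleaned.stage("extinction"), summaries, purity)
    results = rtfmod.rtf_table(cleaned, summaries, catalog, coverage)
    return {
        "summaries": summaries,
        "asv": cleaned,
        "contaminants": contaminants,
        "catalog": catalog,
        "rtf": results,
    }


@dataclasses.dataclass
class RunConfig:
    """Thresholds and scenario settings for one pipeline run.

    Defaults encode the field protocol: 90% read purity for operational
    monocultures, 85% catalog coverage for constitutable communities, a
    2000-read sample filter, the 2%-in->20%-of-blanks contaminant rule, and
    richness bins split at 12 and 26 taxa.
    """

    scenario: str = "null"
    seed: int = 0
    n_communities: int = 20
    richness_min: int = 2
    richness_max: int = 30
    use_dilution_design: bool = False
    noiseless: bool = False
    purity: float = 0.90
    coverage: float = 0.85
    min_reads: int = 2000
    blank_fraction: float = 0.02
    blank_prevalence: float = 0.20
    bins: tuple = ((None, 12), (12, 26), (26, None))
    scenario_overrides: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bins" in raw:
            raw["bins"] = tuple(tuple(b) for b in raw["bins"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["bins"] = [list(b) for b in self.bins]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def scenario_config(self) -> syn.ScenarioConfig:
        sc = syn.ScenarioConfig.preset(self.scenario, seed=self.seed,
                                       **self.scenario_overrides)
        if self.noiseless:
            sc = sc.noiseless()
        return sc


def stage_simulate(config: RunConfig, outdir: Path) -> syn.SyntheticDataset:
    sc = config.scenario_config()
    rng = np.random.default_rng(config.seed)
    richness_list = None
    if not config.use_dilution_design:
        richness_list = np.linspace(
            config.richness_min, config.richness_max, config.n_communities
        ).round().astype(int)
        richness_list = list(richness_list)
        del rng
    ds = syn.simulate_experiment(sc, richness_list=richness_list,
                                 use_dilution_design=config.use_dilution_design)
    ds.write(outdir)
    log.info("simulate: %d samples, %d taxa", len(ds.asv.sample_ids), len(ds.asv.taxon_ids))
    return ds


def stage_measure(outdir: Path) -> pd.DataFrame:
    series = meas.read_timeseries_tsv(outdir / "timeseries.tsv")
    asv = comp.AsvTable.from_tsv(outdir / "asv_table.tsv")
    blank_ids = [s for s in asv.sample_ids if asv.meta.loc[s, "blank"]]
    summaries = meas.summarize_all(series, blank_ids=blank_ids)
    meas.write_summary_tsv(summaries, outdir / "function_summaries.tsv")
    log.info("measure: %d sample summaries", len(summaries))
    return summaries


def stage_compose(config: RunConfig, outdir: Path) -> comp.AsvTable:
    asv = comp.AsvTable.from_tsv(outdir / "asv_table.tsv")
    n0 = len(asv.sample_ids)
    filtered = comp.filter_min_depth(asv, config.min_reads)
    dropped = n0 - len(filtered.sample_ids)
    cleaned, contaminants = comp.remove_contaminants(
        filtered, config.blank_fraction, config.blank_prevalence
    )
    log.info("compose: dropped %d shallow samples, removed %d contaminant ASVs (%s)",
             dropped, len(contaminants), ",".join(contaminants) or "-")
    cleaned.to_tsv(outdir / "asv_table.qc.tsv")
    richness = comp.observed_richness(cleaned.stage("community"))
    richness.to_csv(outdir / "richness.tsv", sep="\t")
    return cleaned


def stage_rtf(config: RunConfig, outdir: Path) -> pd.DataFrame:
    asv = comp.AsvTable.from_tsv(outdir / "asv_table.qc.tsv")
    summaries = meas.read_summary_tsv(outdir / "function_summaries.tsv")
    catalog = rtfmod.identify_monocultures(asv.stage("extinction"), summaries, config.purity)
    cat_out = catalog.copy()
    cat_out.index.name = "taxon_id"
    cat_out.to_csv(outdir / "monoculture_catalog.tsv", sep="\t", float_format="%.10g")
    results = rtfmod.rtf_table(asv, summaries, catalog, config.coverage)
    results.to_csv(outdir / "rtf_results.tsv", sep="\t", index=False, float_format="%.10g")
    n_ok = int(results["constitutable"].sum()) if len(results) else 0
    log.info("rtf: %d/%d communities constitutable (coverage >= %.2f)",
             n_ok, len(results), config.coverage)
    return results


def stage_stats(config: RunConfig, outdir: Path) -> dict:
    results = pd.read_csv(outdir / "rtf_results.tsv", sep="\t")
    summaries = meas.read_summary_tsv(outdir / "function_summaries.tsv")
    ok = results[results["constitutable"] & results["rtf_cell"].notna()]
    summary: dict = {"n_communities": int(len(results)),
                     "n_constitutable": int(len(ok))}

    bin_frames = []
    for fn in ("cell", "protein", "co2"):
        if len(ok) >= 3:
            t = statsmod.richness_bin_tests(ok[f"rtf_{fn}"], ok["richness"], bins=config.bins)
            t.insert(0, "function", fn)
            bin_frames.append(t)
    if bin_frames:
        bins_df = pd.concat(bin_frames, ignore_index=True)
        bins_df.to_csv(outdir / "bin_tests.tsv", sep="\t", index=False, float_format="%.10g")
        summary["rtf_bin_means"] = {
            fn: {row["bin"]: row["mean"] for _, row in g.iterrows()}
            for fn, g in bins_df.groupby("function")
        }

    if len(ok) >= 3:
        summary["mean_rcue_by_bin"] = {
            statsmod._bin_label(lo, hi): float(
                ok.loc[statsmod._bin_mask(ok["richness"].to_numpy(), lo, hi), "mean_rcue"].mean()
            )
            for lo, hi in config.bins
        }

    # diversity-function fits on the measured community summaries
    community = results["community_id"]
    fit_rows = []
    selected = {}
    joint = results.join(summaries, on="community_id")
    for name, col in (("cell", "max_cell_density"), ("protein", "max_total_protein"),
                      ("co2", "total_co2_110h")):
        sub = joint[["richness", col]].dropna()
        if len(sub) >= 4 and sub["richness"].nunique() > 2:
            fr = statsmod.fit_diversity_function(sub["richness"], sub[col])
            selected[name] = fr.selected
            for fam, f in fr.fits.items():
                fit_rows.append({"function": name, "family": fam, "aic": f["aic"],
                                 "rss": f["rss"],
                                 "params": ";".join(f"{p:.10g}" for p in f["params"]),
                                 "selected": fam == fr.selected})
    if fit_rows:
        pd.DataFrame(fit_rows).to_csv(outdir / "fits.tsv", sep="\t", index=False,
                                      float_format="%.10g")
        summary["selected_fit_families"] = selected

    # key-taxa screen on relative abundances of constitutable communities
    asv = comp.AsvTable.from_tsv(outdir / "asv_table.qc.tsv")
    community_table = asv.stage("community")
    keep = [c for c in ok["community_id"] if c in community_table.sample_ids]
    n_hits = 0
    if len(keep) >= 5:
        sub = community_table.select(keep)
        rel = comp.relative_abundance(sub)
        richness = pd.Series(ok.set_index("community_id")["richness"], dtype=float)
        hit_frames = []
        for fn, col in (("cell", "max_cell_density"), ("protein", "max_total_protein")):
            fv = summaries.loc[keep, col]
            hits = statsmod.sliding_window_screen(rel, fv, richness.loc[keep],
                                                  function_name=fn)
            hit_frames.append(hits)
        hits_df = pd.concat(hit_frames, ignore_index=True)
        hits_df[hits_df["hit"]].to_csv(outdir / "window_hits.tsv", sep="\t", index=False,
                                       float_format="%.10g")
        n_hits = int(hits_df["hit"].sum())
    summary["n_window_hits"] = n_hits

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("stats: summary written (%d constitutable communities)", len(ok))
    return summary


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages in order and return the JSON summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    stage_simulate(config, outdir)
    stage_measure(outdir)
    stage_compose(config, outdir)
    stage_rtf(config, outdir)
    return stage_stats(config, outdir)
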