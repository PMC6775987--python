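"""Ground-truthed consumer-resource community simulator.

Emulates the two-stage experiment the RTF framework was designed for: a
regional seawater taxon pool with skewed abundances is 4-fold serially diluted
to assemble replicate communities of decreasing richness; communities grow on
a shared multi-substrate carbon pool (with tunable niche overlap, interference
and complementation); each community is also run to dilution-to-extinction
monocultures; and a measurement layer emits noisy FACS/fluorescence/CO2
time series plus multinomial 16S read tables with blank wells.

Every sample carries exact ground truth (per-taxon uptake S_C,i and conversion
efficiencies in community and monoculture), so the analysis stack can be
validated against known RTF values.

Units: substrate amounts are carbon units (the default pool totals 1);
cells = cue * S * cells_per_carbon; protein = cells * protein_per_cell;
CO2 = (1 - cue) * S in the same carbon units.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import measurements as meas
from .composition import AsvTable

__all__ = [
    "SubstratePool",
    "TaxonSpec",
    "ScenarioConfig",
    "GrowthTruth",
    "SyntheticDataset",
    "build_regional_pool",
    "enumerate_dilution_design",
    "assemble_inoculum",
    "sample_community",
    "simulate_growth",
    "simulate_measurements",
    "simulate_experiment",
]

CONTAMINANT_ID = "CONTAM001"
#: Second kit contaminant that only ever shows up in blank wells.
BLANK_CONTAMINANT_ID = "CONTAM002"
#: Per-taxon cap on low-level cross-talk reads in blank wells.
BLANK_CROSSTALK_FRACTION = 0.01


@dataclasses.dataclass(frozen=True)
class SubstratePool:
    """Total resources available: carbon units per substrate."""

    amounts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        amounts = np.asarray(self.amounts, dtype=float)
        object.__setattr__(self, "amounts", amounts)
        if len(amounts) != len(self.labels):
            raise ValueError("amounts and labels must align")
        if np.any(amounts < 0):
            raise ValueError("substrate amounts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.amounts.sum())


@dataclasses.dataclass(frozen=True)
class TaxonSpec:
    """A simulated taxon's resource-use profile and conversion constants.

    ``use_profile`` holds per-substrate uptake weights (0 = cannot use);
    ``cue`` is the monoculture carbon-use efficiency, bounded by the
    thermodynamic range 0-0.6; ``regional_abundance`` is the taxon's relative
    frequency in the source pool.
    """

    taxon_id: str
    use_profile: np.ndarray
    cue: float
    cells_per_carbon: float
    protein_per_cell: float
    regional_abundance: float

    def __post_init__(self) -> None:
        profile = np.asarray(self.use_profile, dtype=float)
        object.__setattr__(self, "use_profile", profile)
        if np.any(profile < 0):
            raise ValueError("use-profile weights must be non-negative")
        if not profile.any():
            raise ValueError("each taxon must use at least one substrate")
        if not 0.0 <= self.cue <= 0.6:
            raise ValueError("cue must lie in the thermodynamic range [0, 0.6]")


@dataclasses.dataclass
class ScenarioConfig:
    """Generator settings for one simulated experiment.

    ``scenario`` picks an interaction regime; ``interference_strength`` is the
    multiplicative conversion-efficiency penalty per unit niche overlap;
    ``niche_breadth`` is the fraction of substrates each taxon can use. The
    heterogeneity spreads (``cue_sd`` etc.) default to 0: in that regime the
    protein/cell and CO2/cell ratios are equal across taxa, so abundance-based
    per-taxon function attribution is exact (adjustment factors are 1).
    """

    scenario: str = "null"
    n_taxa: int = 60
    n_substrates: int = 20
    niche_breadth: float = 1.0
    interference_strength: float = 0.0
    total_carbon: float = 1.0
    abundance_sigma: float = 1.5
    cue: float = 0.3
    cue_sd: float = 0.0
    cells_per_carbon: float = 1.0e6
    cells_per_carbon_sd: float = 0.0
    protein_per_cell: float = 1.0
    protein_per_cell_sd: float = 0.0
    # measurement layer
    sequencing_depth: int = 20000
    blank_depth: int = 5000
    cv_cells: float = 0.1
    cv_protein: float = 0.1
    cv_co2: float = 0.1
    exact_composition: bool = False
    n_blanks: int = 4
    blank_contaminant_fraction: float = 0.4
    community_contaminant_fraction: float = 0.002
    mono_reps: int = 3
    mono_purity_range: tuple[float, float] = (0.86, 0.995)
    inoculum_cells: float = 1.0e6
    volume_ml: float = meas.DEFAULT_VOLUME_ML
    growth_rate: float = 0.1
    rate_richness_coupling: float = 0.05
    co2_timescale_h: float = 24.0
    baseline_co2_pct_per_h: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("null", "interference", "complementation", "mixed"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.interference_strength <= 1.0:
            raise ValueError("interference_strength must lie in [0, 1]")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")

    @classmethod
    def preset(cls, scenario: str, **overrides) -> "ScenarioConfig":
        """Named interaction regimes.

        null:            full niche overlap, no interference (RTF = 1).
        interference:    full overlap plus an efficiency penalty (RTF < 1).
        complementation: disjoint niches (RTF = richness, RMF = 1).
        mixed:           partial overlap plus moderate interference — both
                         channels of the RTF decomposition active at once.
        """
        base = {
            "null": dict(niche_breadth=1.0, interference_strength=0.0),
            "interference": dict(niche_breadth=1.0, interference_strength=0.5),
            "complementation": dict(niche_breadth=0.0, interference_strength=0.0),
            "mixed": dict(niche_breadth=0.35, interference_strength=0.4),
        }[scenario]
        base.update(overrides)
        return cls(scenario=scenario, **base)

    def noiseless(self) -> "ScenarioConfig":
        """Copy with all noise channels off and exact read composition."""
        return dataclasses.replace(
            self, cv_cells=0.0, cv_protein=0.0, cv_co2=0.0, exact_composition=True,
            mono_purity_range=(1.0, 1.0),
        )


def build_regional_pool(
    n_taxa: int,
    n_substrates: int,
    niche_breadth: float = 0.35,
    seed: int | None = None,
    config: ScenarioConfig | None = None,
) -> tuple[list[TaxonSpec], SubstratePool]:
    """Draw a regional taxon pool and the shared substrate pool.

    Regional abundances are log-normal (configurable sigma), matching the
    skewed rank-abundance curves of filtered seawater. Each taxon uses
    max(1, round(niche_breadth * n_substrates)) substrates; the first usable
    substrate is assigned round-robin (taxon i anchors substrate i mod n), so
    every substrate has a consumer whenever n_taxa >= n_substrates, and a
    breadth of one substrate with n_taxa <= n_substrates gives fully disjoint
    (complementary) niches.
    """
    if n_taxa < 1 or n_substrates < 1:
        raise ValueError("n_taxa and n_substrates must be positive")
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k_use = max(1, int(round(niche_breadth * n_substrates)))
    k_use = min(k_use, n_substrates)

    raw = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n_taxa)
    abundances = raw / raw.sum()
    cues = np.clip(rng.normal(cfg.cue, cfg.cue_sd, size=n_taxa), 0.01, 0.6)
    cpc = cfg.cells_per_carbon * np.exp(
        rng.normal(0.0, cfg.cells_per_carbon_sd, size=n_taxa)
    )
    ppc = cfg.protein_per_cell * np.exp(
        rng.normal(0.0, cfg.protein_per_cell_sd, size=n_taxa)
    )

    taxa: list[TaxonSpec] = []
    width = max(4, len(str(n_taxa)))
    for i in range(n_taxa):
        profile = np.zeros(n_substrates)
        anchor = i % n_substrates
        others = [s for s in range(n_substrates) if s != anchor]
        extra = rng.choice(others, size=k_use - 1, replace=False) if k_use > 1 else []
        used = np.concatenate([[anchor], np.asarray(extra, dtype=int)]).astype(int)
        profile[used] = rng.uniform(0.5, 1.5, size=len(used))
        taxa.append(
            TaxonSpec(
                taxon_id=f"ASV{i + 1:0{width}d}",
                use_profile=profile,
                cue=float(cues[i]),
                cells_per_carbon=float(cpc[i]),
                protein_per_cell=float(ppc[i]),
                regional_abundance=float(abundances[i]),
            )
        )
    pool = SubstratePool(
        amounts=np.full(n_substrates, cfg.total_carbon / n_substrates),
        labels=tuple(f"S{r + 1:03d}" for r in range(n_substrates)),
    )
    return taxa, pool


def enumerate_dilution_design(
    n_replicates: int = 15,
    fold: int = 4,
    levels: Sequence[int] | None = None,
    extra: dict | None = None,
) -> pd.DataFrame:
    """One record per inoculum vessel of the serial-dilution design.

    Defaults reproduce the field design: 15 undiluted communities, 15 at each
    4-fold dilution level 4^2 .. 4^11, plus 5 and 15 extra sub-communities at
    the two highest levels — 185 vessels in total.
    """
    if levels is None:
        levels = [fold**e for e in range(2, 12)]
    if extra is None and levels == [fold**e for e in range(2, 12)]:
        extra = {fold**10: 5, fold**11: 15}
    extra = extra or {}
    records = []
    for rep in range(1, n_replicates + 1):
        records.append({"replicate": rep, "dilution_factor": 1})
    for level in levels:
        for rep in range(1, n_replicates + 1):
            records.append({"replicate": rep, "dilution_factor": int(level)})
    for level, count in sorted(extra.items()):
        for j in range(1, count + 1):
            records.append({"replicate": n_replicates + j, "dilution_factor": int(level)})
    df = pd.DataFrame(records, columns=["replicate", "dilution_factor"])
    df.insert(0, "vessel", [f"V{k + 1:03d}" for k in range(len(df))])
    return df


def assemble_inoculum(
    taxa: Sequence[TaxonSpec],
    dilution_factor: float,
    inoculum_cells: float = 1.0e6,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Founder cell counts after diluting the regional pool.

    round(inoculum_cells / dilution_factor) cells are drawn multinomially from
    the regional abundances; members are taxa with at least one founder.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    if inoculum_cells < 0:
        raise ValueError("inoculum_cells must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_cells = int(round(inoculum_cells / dilution_factor))
    p = np.array([t.regional_abundance for t in taxa])
    p = p / p.sum()
    founders = rng.multinomial(n_cells, p) if n_cells > 0 else np.zeros(len(taxa), dtype=int)
    present = founders > 0
    return pd.DataFrame(
        {
            "taxon_id": [t.taxon_id for t, m in zip(taxa, present) if m],
            "founder_cells": founders[present],
        }
    )


def sample_community(
    taxa: Sequence[TaxonSpec],
    richness: int,
    rng: np.random.Generator | int | None = None,
) -> list[TaxonSpec]:
    """Draw a community of exactly ``richness`` members, weighted by regional abundance."""
    if not 1 <= richness <= len(taxa):
        raise ValueError("richness must lie in [1, n_taxa]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = np.array([t.regional_abundance for t in taxa])
    idx = rng.choice(len(taxa), size=richness, replace=False, p=p / p.sum())
    return [taxa[i] for i in sorted(idx)]


@dataclasses.dataclass
class GrowthTruth:
    """Ground truth for one grown sample.

    ``per_taxon`` columns: taxon_id, s_mono (S_i), s_comm (S_C,i), overlap,
    cue_mono, cue_comm, cells/protein/co2 (community values) and the _mono
    counterparts, plus the ratios s_ratio and a_ratio_{cell,protein,co2}.
    ``rtf_true`` holds sum_i (a_C,i/a_i)(S_C,i/S_i) per function.
    """

    per_taxon: pd.DataFrame
    uptake_sum: float  # sum_i S_C,i / S_i
    sbar: float  # uptake_sum / N
    abar: dict  # mean a_C,i/a_i per function
    rtf_true: dict  # per function

    @property
    def totals(self) -> dict:
        pt = self.per_taxon
        return {
            "cells": float(pt["cells"].sum()),
            "protein": float(pt["protein"].sum()),
            "co2": float(pt["co2"].sum()),
        }


def simulate_growth(
    members: Sequence[TaxonSpec],
    substrates: SubstratePool,
    scenario: ScenarioConfig,
) -> GrowthTruth:
    """Grow a community on the shared pool and return exact ground truth.

    Each substrate's carbon is split among capable members proportionally to
    their use-profile weights (equal weights -> equal split). Interference
    multiplies every member's conversion efficiency by
    (1 - interference_strength * mean niche overlap), where a taxon's overlap
    is the carbon-weighted fraction of its fundamental niche shared with at
    least one other member; the penalty is applied community-wide so the two
    channels of the RTF decomposition (uptake vs efficiency) stay independent.
    A single-member call is the monoculture: full pool access, no penalty.
    """
    if len(members) == 0:
        raise ValueError("members must be nonempty")
    amounts = substrates.amounts
    if np.any(amounts < 0):
        raise ValueError("substrate amounts must be non-negative")
    W = np.stack([m.use_profile for m in members])  # (k, n_sub)
    capable = W > 0
    colsum = W.sum(axis=0)
    share = np.divide(W, colsum, out=np.zeros_like(W), where=colsum > 0)
    s_comm = share @ amounts
    s_mono = capable @ amounts

    n_consumers = capable.sum(axis=0)
    shared = capable & (n_consumers >= 2)
    with np.errstate(invalid="ignore"):
        overlap = np.divide(shared @ amounts, s_mono, out=np.zeros(len(members)), where=s_mono > 0)
    mean_overlap = float(overlap.mean()) if len(members) > 1 else 0.0
    penalty = 1.0 - scenario.interference_strength * mean_overlap

    cue_mono = np.array([m.cue for m in members])
    cue_comm = np.clip(cue_mono * penalty, 1e-9, 0.6)
    cpc = np.array([m.cells_per_carbon for m in members])
    ppc = np.array([m.protein_per_cell for m in members])

    cells = cue_comm * s_comm * cpc
    protein = cells * ppc
    co2 = (1.0 - cue_comm) * s_comm
    cells_mono = cue_mono * s_mono * cpc
    protein_mono = cells_mono * ppc
    co2_mono = (1.0 - cue_mono) * s_mono

    with np.errstate(invalid="ignore", divide="ignore"):
        s_ratio = np.divide(s_comm, s_mono, out=np.zeros(len(members)), where=s_mono > 0)
    a_cell = cue_comm / cue_mono
    a_protein = a_cell.copy()
    a_co2 = (1.0 - cue_comm) / (1.0 - cue_mono)

    per_taxon = pd.DataFrame(
        {
            "taxon_id": [m.taxon_id for m in members],
            "s_mono": s_mono,
            "s_comm": s_comm,
            "overlap": overlap,
            "cue_mono": cue_mono,
            "cue_comm": cue_comm,
            "cells": cells,
            "protein": protein,
            "co2": co2,
            "cells_mono": cells_mono,
            "protein_mono": protein_mono,
            "co2_mono": co2_mono,
            "s_ratio": s_ratio,
            "a_ratio_cell": a_cell,
            "a_ratio_protein": a_protein,
            "a_ratio_co2": a_co2,
        }
    )
    uptake_sum = float(s_ratio.sum())
    rtf_true = {
        "cell": float(np.sum(a_cell * s_ratio)),
        "protein": float(np.sum(a_protein * s_ratio)),
        "co2": float(np.sum(a_co2 * s_ratio)),
    }
    abar = {
        "cell": float(a_cell.mean()),
        "protein": float(a_protein.mean()),
        "co2": float(a_co2.mean()),
    }
    return GrowthTruth(
        per_taxon=per_taxon,
        uptake_sum=uptake_sum,
        sbar=uptake_sum / len(members),
        abar=abar,
        rtf_true=rtf_true,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise at coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclasses.dataclass
class SyntheticDataset:
    """Bundle of all simulated outputs plus ground truth."""

    asv: AsvTable
    timeseries: pd.DataFrame
    truth_per_taxon: pd.DataFrame
    truth_community: pd.DataFrame
    config: ScenarioConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        import yaml

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.asv.to_tsv(out / "asv_table.tsv")
        meas.write_timeseries_tsv(self.timeseries, out / "timeseries.tsv")
        self.truth_per_taxon.to_csv(out / "truth_per_taxon.tsv", sep="\t", index=False,
                                    float_format="%.10g")
        self.truth_community.to_csv(out / "truth_community.tsv", sep="\t", index=False,
                                    float_format="%.10g")
        cfg = dataclasses.asdict(self.config)
        cfg["mono_purity_range"] = list(cfg["mono_purity_range"])
        with open(out / "scenario.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def simulate_measurements(
    sample_truths: Sequence[tuple[str, str, GrowthTruth]],
    scenario: ScenarioConfig,
    rng: np.random.Generator | int | None = None,
    taxa: Sequence[TaxonSpec] | None = None,
    mono_purity: dict | None = None,
) -> tuple[pd.DataFrame, AsvTable]:
    """Emit noisy time series and a read table for a set of grown samples.

    ``sample_truths`` holds (sample_id, stage, truth) triples. Trajectories
    are exponential-to-plateau in cell count (the plateau is the true carrying
    capacity, so max-within-110 h recovers it exactly when noise is off) and
    the cumulative CO2 release follows one shared saturating schedule, so any
    windowed total is the same fixed fraction of the full total for every
    sample. Noise is one multiplicative log-normal factor per sample and
    channel, mimicking plate-level calibration error of the bead/protein
    standards; reads are multinomial at the configured depth (or exact scaled
    fractions when ``exact_composition``), blanks carry a planted contaminant.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    times = np.array(meas.TIME_POINTS_H)
    vol = scenario.volume_ml
    tau = scenario.co2_timescale_h
    g = (1.0 - np.exp(-times / tau)) / (1.0 - np.exp(-times[-1] / tau))

    all_taxa = taxa if taxa is not None else None
    taxon_ids: list[str] = []
    if all_taxa is not None:
        taxon_ids = [t.taxon_id for t in all_taxa]
    else:
        seen = {}
        for _, _, truth in sample_truths:
            for tid in truth.per_taxon["taxon_id"]:
                seen[tid] = None
        taxon_ids = sorted(seen)
    columns = taxon_ids + [CONTAMINANT_ID, BLANK_CONTAMINANT_ID]
    col_index = {c: k for k, c in enumerate(columns)}

    ts_rows = []
    count_rows = []
    meta_rows = []

    def emit_counts(sample_id: str, stage: str, blank: bool, fractions: np.ndarray,
                    depth: int) -> None:
        if scenario.exact_composition:
            counts = np.round(fractions * 1e12).astype(np.int64)
        else:
            depth_eff = max(int(rng.lognormal(np.log(depth), 0.2)), 1)
            counts = rng.multinomial(depth_eff, fractions / fractions.sum())
        count_rows.append(counts)
        meta_rows.append({"sample_id": sample_id, "blank": blank, "stage": stage})

    for sample_id, stage, truth in sample_truths:
        totals = truth.totals
        k_cells = totals["cells"]
        ppc_eff = totals["protein"] / k_cells if k_cells > 0 else 0.0
        richness = len(truth.per_taxon)
        rate = scenario.growth_rate * (1.0 + scenario.rate_richness_coupling * (richness - 1))
        c0 = k_cells / 30.0
        traj = np.minimum(c0 * np.exp(rate * times), k_cells)
        eta_c, eta_p, eta_o = (
            _lognormal_factor(rng, scenario.cv_cells, 1)[0],
            _lognormal_factor(rng, scenario.cv_protein, 1)[0],
            _lognormal_factor(rng, scenario.cv_co2, 1)[0],
        )
        dens = traj / vol * eta_c
        ppc_series = np.full_like(times, ppc_eff * eta_p)
        cum = totals["co2"] * g
        d572 = [np.nan]
        for k in range(1, len(times)):
            pct = (cum[k] - cum[k - 1]) / vol * eta_o
            pct += scenario.baseline_co2_pct_per_h * (times[k] - times[k - 1])
            d572.append(meas.absorbance_from_co2(pct))
        for k, t in enumerate(times):
            ts_rows.append((sample_id, t, dens[k], ppc_series[k], d572[k]))

        fractions = np.zeros(len(columns))
        pt = truth.per_taxon
        cell_frac = pt["cells"].to_numpy() / k_cells
        if stage == "extinction" and mono_purity is not None and sample_id in mono_purity:
            purity, minors = mono_purity[sample_id]
            dom = pt["taxon_id"].iloc[0]
            fractions[col_index[dom]] = purity
            minor_mass = 1.0 - purity
            if minors and minor_mass > 0:
                for m in minors:
                    fractions[col_index[m]] += minor_mass / len(minors)
        else:
            for tid, f in zip(pt["taxon_id"], cell_frac):
                fractions[col_index[tid]] = f
        cf = scenario.community_contaminant_fraction
        if cf > 0:
            fractions *= 1.0 - cf
            fractions[col_index[CONTAMINANT_ID]] += cf
        emit_counts(sample_id, stage, False, fractions, scenario.sequencing_depth)

    # blank wells: indicator baseline only; reads dominated by kit
    # contaminants with low-level cross-talk (capped per taxon so real taxa
    # stay below the contaminant-filter threshold)
    n_real = len(taxon_ids)
    crosstalk = min(BLANK_CROSSTALK_FRACTION,
                    (1.0 - scenario.blank_contaminant_fraction) / max(n_real, 1))
    for b in range(scenario.n_blanks):
        sample_id = f"BLANK{b + 1:02d}"
        eta_o = _lognormal_factor(rng, scenario.cv_co2, 1)[0]
        d572 = [np.nan]
        for k in range(1, len(times)):
            pct = scenario.baseline_co2_pct_per_h * (times[k] - times[k - 1]) * eta_o
            d572.append(meas.absorbance_from_co2(pct))
        for k, t in enumerate(times):
            ts_rows.append((sample_id, t, 0.0, 0.0, d572[k]))
        fractions = np.zeros(len(columns))
        bf = scenario.blank_contaminant_fraction
        fractions[col_index[CONTAMINANT_ID]] = bf
        if n_real:
            fractions[:n_real] = crosstalk
        fractions[col_index[BLANK_CONTAMINANT_ID]] = 1.0 - fractions.sum()
        emit_counts(sample_id, "community", True, fractions, scenario.blank_depth)

    timeseries = pd.DataFrame(
        ts_rows,
        columns=["sample_id", "time_h", "cells_per_ml", "protein_fluor_per_cell", "delta572"],
    )
    counts = pd.DataFrame(
        np.stack(count_rows), columns=columns,
        index=[m["sample_id"] for m in meta_rows],
    ).astype(np.int64)
    counts.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return timeseries, AsvTable(counts, meta)


def simulate_experiment(
    config: ScenarioConfig,
    richness_list: Sequence[int] | None = None,
    use_dilution_design: bool = False,
) -> SyntheticDataset:
    """End-to-end generation: pool, communities, monocultures, measurements.

    Communities come either from an explicit ``richness_list`` (one community
    per entry, members drawn by regional abundance) or, when
    ``use_dilution_design`` is set, from the full 185-vessel serial-dilution
    design. Every taxon occurring in any community also gets
    ``config.mono_reps`` dilution-to-extinction monoculture samples.
    """
    master = np.random.SeedSequence(config.seed)
    pool_seed, assemble_seed, meas_seed, purity_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(4)
    )
    taxa, substrates = build_regional_pool(
        config.n_taxa, config.n_substrates, config.niche_breadth, seed=pool_seed, config=config
    )
    by_id = {t.taxon_id: t for t in taxa}
    rng = np.random.default_rng(assemble_seed)

    communities: list[tuple[str, list[TaxonSpec]]] = []
    if use_dilution_design:
        design = enumerate_dilution_design()
        for _, row in design.iterrows():
            founders = assemble_inoculum(
                taxa, row["dilution_factor"], config.inoculum_cells, rng
            )
            members = [by_id[t] for t in founders["taxon_id"]]
            if members:
                communities.append((f"C{row['vessel']}", members))
    else:
        if richness_list is None:
            richness_list = list(np.linspace(2, 30, 20).round().astype(int))
        for j, k in enumerate(richness_list):
            members = sample_community(taxa, int(k), rng)
            communities.append((f"C{j + 1:03d}", members))

    sample_truths: list[tuple[str, str, GrowthTruth]] = []
    truth_comm_rows = []
    truth_taxon_frames = []
    for cid, members in communities:
        truth = simulate_growth(members, substrates, config)
        sample_truths.append((cid, "community", truth))
        truth_comm_rows.append(
            {
                "sample_id": cid,
                "richness": len(members),
                "uptake_sum_true": truth.uptake_sum,
                "sbar_true": truth.sbar,
                "abar_cell": truth.abar["cell"],
                "abar_protein": truth.abar["protein"],
                "abar_co2": truth.abar["co2"],
                "rtf_true_cell": truth.rtf_true["cell"],
                "rtf_true_protein": truth.rtf_true["protein"],
                "rtf_true_co2": truth.rtf_true["co2"],
            }
        )
        pt = truth.per_taxon.copy()
        pt.insert(0, "sample_id", cid)
        truth_taxon_frames.append(pt)

    mono_taxa = sorted({m.taxon_id for _, members in communities for m in members})
    purity_rng = np.random.default_rng(purity_seed)
    mono_purity: dict[str, tuple[float, list[str]]] = {}
    for tid in mono_taxa:
        for rep in range(1, config.mono_reps + 1):
            sid = f"M{tid}r{rep}"
            truth = simulate_growth([by_id[tid]], substrates, config)
            sample_truths.append((sid, "extinction", truth))
            lo, hi = config.mono_purity_range
            purity = float(purity_rng.uniform(lo, hi))
            others = [t for t in mono_taxa if t != tid]
            minors = (
                list(purity_rng.choice(others, size=min(3, len(others)), replace=False))
                if purity < 1.0 and others
                else []
            )
            mono_purity[sid] = (purity, minors)

    timeseries, asv = simulate_measurements(
        sample_truths, config, rng=np.random.default_rng(meas_seed), taxa=taxa,
        mono_purity=mono_purity,
    )
    return SyntheticDataset(
        asv=asv,
        timeseries=timeseries,
        truth_per_taxon=pd.concat(truth_taxon_frames, ignore_index=True)
        if truth_taxon_frames
        else pd.DataFrame(),
        truth_community=pd.DataFrame(truth_comm_rows),
        config=config,
    )
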