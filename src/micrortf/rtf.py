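"""Relative total function (RTF): the core community-vs-monoculture framework.

RTF_C = sum_i F_C,i / F_i compares each taxon's function inside a community to
its monoculture function; it is 1 when community function is just the sum of
independent individual contributions, above 1 under net positive interactions
(e.g. niche complementation) and below 1 under net negative ones (e.g.
interference competition). RMF_C = RTF_C / N_C is the same quantity for the
average member. Because RTF_C factorizes into mean relative conversion
efficiency times relative total resource uptake, the pair
(RTF_CO2, RTF_biomass) brackets the community's relative total uptake, and
their ratio yields the community's carbon-use efficiency relative to
monoculture expectation (rCUE).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import AsvTable, observed_richness, relative_abundance

__all__ = [
    "FUNCTION_COLUMNS",
    "DegenerateMonocultureError",
    "RTFResult",
    "DecompositionBounds",
    "RCUEEstimate",
    "identify_monocultures",
    "assess_constitutable",
    "per_taxon_functions",
    "compute_rtf",
    "decomposition_bounds",
    "adjustment_factors",
    "estimate_rcue",
    "rtf_table",
]

#: RTF function name -> FunctionSummary column. CO2 uses the 0-40 h window
#: because composition is measured at early stationary phase (~40 h).
FUNCTION_COLUMNS = {
    "cell": "max_cell_density",
    "protein": "max_total_protein",
    "co2": "total_co2_40h",
}


class DegenerateMonocultureError(ValueError):
    """A catalog monoculture function is zero; the RTF ratio is undefined."""


@dataclasses.dataclass
class RTFResult:
    community_id: str
    n_c: int
    coverage: float
    constitutable: bool
    rtf: dict
    rmf: dict


@dataclasses.dataclass
class DecompositionBounds:
    """Bounds on relative total resource uptake implied by two RTFs.

    Because the CO2 and biomass conversion efficiencies must deviate from the
    monoculture in opposite directions, sum_i S_C,i/S_i lies between
    RTF_C(CO2) and RTF_C(biomass); dividing by N_C bounds the mean per-taxon
    uptake S-bar. ``regime`` is "complementation" when the whole interval is
    above 1, "competition" when below 1, else "indeterminate".
    """

    uptake_low: float
    uptake_high: float
    sbar_low: float
    sbar_high: float
    regime: str


@dataclasses.dataclass
class RCUEEstimate:
    ratio_rtf: float
    cue_grid: np.ndarray
    rcue: np.ndarray
    mean_rcue: float


def identify_monocultures(
    extinction: AsvTable,
    summaries: pd.DataFrame,
    purity: float = 0.90,
    agg: str = "mean",
) -> pd.DataFrame:
    """Build the monoculture function catalog from dilution-to-extinction samples.

    A sample qualifies as an operational monoculture when its most abundant
    ASV holds at least ``purity`` of the reads; its measured functions are
    taken as that taxon's monoculture functions. Multiple qualifying samples
    per taxon are aggregated (mean by default, median via ``agg``).

    Returns a DataFrame indexed by taxon id with the FunctionSummary columns
    plus ``n_samples`` and ``purity`` (the best purity achieved).
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    rel = relative_abundance(extinction)
    rows = []
    df_sample_ids: list[str] = []
    for sid in extinction.sample_ids:
        if sid not in summaries.index:
            continue
        r = rel.loc[sid]
        top_taxon = r.idxmax()
        top_frac = float(r.max())
        if top_frac >= purity:
            rec = summaries.loc[sid].to_dict()
            rec.update({"taxon_id": top_taxon, "purity": top_frac})
            rows.append(rec)
            df_sample_ids.append(sid)
    if not rows:
        empty = pd.DataFrame(columns=list(FUNCTION_COLUMNS.values()) + ["n_samples", "purity"])
        empty.attrs["sample_ids"] = []
        return empty
    df = pd.DataFrame(rows)
    value_cols = [c for c in df.columns if c not in ("taxon_id", "purity")]
    grouped = df.groupby("taxon_id")
    catalog = getattr(grouped[value_cols], agg)()
    catalog["n_samples"] = grouped.size()
    catalog["purity"] = grouped["purity"].max()
    catalog = catalog.sort_index()
    catalog.attrs["sample_ids"] = sorted(df_sample_ids)
    return catalog


def assess_constitutable(
    abundances: pd.Series,
    catalog_taxa: Iterable[str],
    coverage: float = 0.85,
) -> tuple[float, pd.Series, bool]:
    """Coverage of a community by the monoculture catalog, with renormalization.

    ``abundances`` holds the community's relative abundances; coverage is the
    summed abundance of cataloged taxa. The community is constitutable when
    coverage >= ``coverage`` (the remaining taxa are assumed to behave like the
    covered part). Renormalized abundances over cataloged taxa sum to 1.
    """
    catalog_taxa = set(catalog_taxa)
    covered = abundances[[t for t in abundances.index if t in catalog_taxa]]
    covered = covered[covered > 0]
    cov = float(covered.sum())
    renorm = covered / cov if cov > 0 else covered
    return cov, renorm, cov >= coverage


def per_taxon_functions(
    community_functions: Mapping[str, float],
    renormalized_abundances: pd.Series,
) -> pd.DataFrame:
    """Attribute community functions to taxa: F_C,i = F_C * R_C,i.

    Exact for cell counts; for protein and CO2 it assumes near-equal per-cell
    ratios across taxa (adjustment factor 1), the regime checked by
    :func:`adjustment_factors`.
    """
    for name, value in community_functions.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"missing community function value for {name!r}")
    out = pd.DataFrame(
        {
            name: renormalized_abundances * value
            for name, value in community_functions.items()
        }
    )
    out.index.name = "taxon_id"
    return out


def compute_rtf(
    per_taxon: pd.DataFrame,
    catalog: pd.DataFrame,
    community_id: str = "",
    coverage: float = float("nan"),
    constitutable: bool = True,
) -> RTFResult:
    """RTF and RMF per function from per-taxon functions and the catalog.

    Every taxon in ``per_taxon`` must be cataloged; N_C is the number of
    cataloged taxa entering the (renormalized) sum.
    """
    missing = [t for t in per_taxon.index if t not in catalog.index]
    if missing:
        raise KeyError(f"taxa absent from monoculture catalog: {missing}")
    n_c = len(per_taxon)
    rtf = {}
    for col in per_taxon.columns:
        f_i = catalog.loc[per_taxon.index, col].to_numpy(dtype=float)
        if np.any(f_i <= 0):
            raise DegenerateMonocultureError(f"non-positive monoculture {col}")
        rtf[col] = float(np.sum(per_taxon[col].to_numpy(dtype=float) / f_i))
    rmf = {k: v / n_c for k, v in rtf.items()}
    return RTFResult(
        community_id=community_id,
        n_c=n_c,
        coverage=coverage,
        constitutable=constitutable,
        rtf=rtf,
        rmf=rmf,
    )


def decomposition_bounds(rtf_co2: float, rtf_biomass: float, n_c: int) -> DecompositionBounds:
    """Interval for relative total uptake from the CO2 and biomass RTFs."""
    lo, hi = sorted((float(rtf_co2), float(rtf_biomass)))
    if lo > 1.0:
        regime = "complementation"
    elif hi < 1.0:
        regime = "competition"
    else:
        regime = "indeterminate"
    return DecompositionBounds(
        uptake_low=lo,
        uptake_high=hi,
        sbar_low=lo / n_c,
        sbar_high=hi / n_c,
        regime=regime,
    )


def adjustment_factors(
    catalog: pd.DataFrame,
    memberships: Mapping[str, Sequence[str]],
    functions: Sequence[str] = ("max_total_protein", "total_co2_40h"),
    cell_column: str = "max_cell_density",
) -> pd.DataFrame:
    """Null-model adjustment factors for the F_C * R_C,i approximation.

    For taxon i in community C and function f, the factor is the taxon's
    per-cell function ratio divided by the community mean per-cell ratio:
    (F_i(f)/F_i(cell)) / mean_j(F_j(f)/F_j(cell)). Attribution by relative
    abundance is exact when every factor is 1; the field expectation is that
    most factors fall in [0.5, 2]. Returns one row per
    (community, taxon, function) with the factor and an ``in_range`` flag.
    """
    rows = []
    for cid, members in memberships.items():
        members = [t for t in members if t in catalog.index]
        if not members:
            continue
        cells = catalog.loc[members, cell_column].to_numpy(dtype=float)
        for f in functions:
            per_cell = catalog.loc[members, f].to_numpy(dtype=float) / cells
            mean_ratio = per_cell.mean()
            for t, r in zip(members, per_cell):
                factor = r / mean_ratio if mean_ratio > 0 else np.nan
                rows.append(
                    {
                        "community_id": cid,
                        "taxon_id": t,
                        "function": f,
                        "factor": factor,
                        "in_range": bool(0.5 <= factor <= 2.0),
                    }
                )
    return pd.DataFrame(rows, columns=["community_id", "taxon_id", "function", "factor", "in_range"])


def estimate_rcue(
    rtf_co2: float,
    rtf_protein: float,
    grid: tuple[float, float, float] = (0.0, 0.6, 0.01),
) -> RCUEEstimate:
    """Relative-to-expected carbon use efficiency from the RTF ratio.

    rCUE = 1 / (Ratio * (1 - CUE) + CUE) with Ratio = RTF_CO2 / RTF_protein,
    evaluated on an inclusive grid of candidate monoculture CUE values
    (default 0 to 0.6 in steps of 0.01, the thermodynamically plausible
    range); the grid mean is the point estimate.
    """
    if rtf_co2 <= 0 or rtf_protein <= 0:
        raise ValueError("RTF values must be positive")
    lo, hi, step = grid
    n = int(round((hi - lo) / step)) + 1
    cue = lo + step * np.arange(n)
    ratio = rtf_co2 / rtf_protein
    rcue = 1.0 / (ratio * (1.0 - cue) + cue)
    return RCUEEstimate(
        ratio_rtf=float(ratio),
        cue_grid=cue,
        rcue=rcue,
        mean_rcue=float(rcue.mean()),
    )


def rtf_table(
    table: AsvTable,
    summaries: pd.DataFrame,
    catalog: pd.DataFrame,
    coverage: float = 0.85,
    functions: Mapping[str, str] = FUNCTION_COLUMNS,
) -> pd.DataFrame:
    """Per-community RTF/RMF/bounds/rCUE table for all community-stage samples.

    Samples already used in the monoculture catalog are excluded from the
    community side to avoid self-comparison. Communities whose catalog
    coverage falls below the threshold are reported with NaN RTFs, never
    imputed.
    """
    community = table.stage("community")
    used_in_catalog = set(catalog.attrs.get("sample_ids", ()))
    rel = relative_abundance(community)
    richness = observed_richness(community)
    rows = []
    for cid in community.sample_ids:
        if cid not in summaries.index or cid in used_in_catalog:
            continue
        cov, renorm, ok = assess_constitutable(rel.loc[cid], catalog.index, coverage)
        row: dict = {
            "community_id": cid,
            "richness": int(richness.loc[cid]),
            "coverage": cov,
            "constitutable": ok,
            "n_c": len(renorm),
        }
        if ok and len(renorm) > 0:
            f_c = {col: float(summaries.loc[cid, col]) for col in functions.values()}
            per_taxon = per_taxon_functions(f_c, renorm)
            res = compute_rtf(per_taxon, catalog, cid, cov, ok)
            for name, col in functions.items():
                row[f"rtf_{name}"] = res.rtf[col]
                row[f"rmf_{name}"] = res.rmf[col]
            bounds = decomposition_bounds(
                res.rtf[functions["co2"]], res.rtf[functions["protein"]], res.n_c
            )
            row.update(
                {
                    "uptake_low": bounds.uptake_low,
                    "uptake_high": bounds.uptake_high,
                    "sbar_low": bounds.sbar_low,
                    "sbar_high": bounds.sbar_high,
                    "regime": bounds.regime,
                }
            )
            est = estimate_rcue(res.rtf[functions["co2"]], res.rtf[functions["protein"]])
            row["ratio_rtf"] = est.ratio_rtf
            row["mean_rcue"] = est.mean_rcue
        else:
            for name in functions:
                row[f"rtf_{name}"] = np.nan
                row[f"rmf_{name}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
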