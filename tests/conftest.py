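import numpy as np
import pandas as pd
import pytest

from micrortf import pipeline, synthetic as syn


def build_two_taxon_case(interference: float, niche_breadth: float, n_substrates: int):
    """Two-taxon worked example: shared or disjoint niches, optional interference.

    Returns (ground truth, analysis dict) for a noiseless end-to-end run:
    community + pure monocultures -> measurements -> QC -> catalog -> RTF.
    """
    sc = syn.ScenarioConfig(
        scenario="null",
        n_taxa=2,
        n_substrates=n_substrates,
        niche_breadth=niche_breadth,
        interference_strength=interference,
        seed=1,
    ).noiseless()
    taxa, pool = syn.build_regional_pool(2, n_substrates, niche_breadth, seed=1, config=sc)
    truth = syn.simulate_growth(taxa, pool, sc)
    samples = [("C001", "community", truth)]
    purity = {}
    for t in taxa:
        sid = f"M{t.taxon_id}r1"
        samples.append((sid, "extinction", syn.simulate_growth([t], pool, sc)))
        purity[sid] = (1.0, [])
    ts, asv = syn.simulate_measurements(
        samples, sc, rng=np.random.default_rng(2), taxa=taxa, mono_purity=purity
    )
    ds = syn.SyntheticDataset(
        asv=asv,
        timeseries=ts,
        truth_per_taxon=truth.per_taxon,
        truth_community=pd.DataFrame(),
        config=sc,
    )
    return truth, pipeline.analyze_dataset(ds)


@pytest.fixture(scope="session")
def shared_pool_pair():
    """Two identical taxa equally splitting one fully shared pool."""
    return build_two_taxon_case(0.0, 1.0, 1)


@pytest.fixture(scope="session")
def interference_pair():
    """Identical niches with a 0.5 efficiency penalty at full overlap."""
    return build_two_taxon_case(0.5, 1.0, 1)


@pytest.fixture(scope="session")
def complementation_pair():
    """Two taxa with fully disjoint single-substrate niches."""
    return build_two_taxon_case(0.0, 0.5, 2)


@pytest.fixture(scope="session")
def noiseless_mixed_run():
    """200-community noiseless mixed-scenario experiment with full analysis."""
    sc = syn.ScenarioConfig.preset("mixed", seed=5).noiseless()
    richness = list(np.linspace(2, 30, 200).round().astype(int))
    ds = syn.simulate_experiment(sc, richness_list=richness)
    out = pipeline.analyze_dataset(ds)
    out["dataset"] = ds
    return out
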