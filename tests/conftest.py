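import warnings

import numpy as np
import pandas as pd
import pytest

import generescue as gr

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_sim():
    """One 5000-gene simulation at study defaults, shared across tests."""
    cfg = gr.SimConfig(n_genes=5000, seed=11)
    counts, samples, effects = gr.simulate_counts(cfg)
    return cfg, counts, samples, effects


@pytest.fixture(scope="session")
def default_de(default_sim):
    """Nipbl-vs-WT differential expression on the shared simulation."""
    _, counts, samples, _ = default_sim
    return gr.run_de(counts, samples, ("NipblHet", "WT"))


@pytest.fixture(scope="session")
def small_sim():
    cfg = gr.SimConfig(n_genes=300, seed=4)
    counts, samples, effects = gr.simulate_counts(cfg)
    return cfg, counts, samples, effects


@pytest.fixture()
def toy_profile():
    """Hand-sized genotype-mean profile with known effect structure."""
    return pd.DataFrame(
        {
            "WT": [100.0, 100.0, 50.0, 0.0],
            "WaplHet": [200.0, 100.0, 25.0, 0.0],
            "NipblHet": [200.0, 50.0, 100.0, 0.0],
            "Double": [100.0, 50.0, 50.0, 0.0],
        },
        index=["up_rescued", "down_unrescued", "mixed", "silent"],
    )


def rescue_cohorts(seed0: int = 31, n_genes: int = 400, delta_cut: float = 0.5):
    """Three low-noise cohorts with rescue_r 0 / 0.5 / 1 and known classes.

    Strong effects (sigma_u 0.5, |delta_N| > delta_cut), high expression and
    unit size factors keep per-gene count noise well below the class spacing,
    which is the regime where cluster-level class calls should recover the
    generating class.
    """
    cohorts = {0.0: "complete", 0.5: "partial", 1.0: "none"}
    counts_list, truth = [], {}
    samples = None
    for i, (r, grade) in enumerate(cohorts.items()):
        cfg = gr.SimConfig(
            n_genes=n_genes, pi_dys=1.0, rescue_r=r, sigma_u=0.5,
            sigma_resid_effect=0.01, baseline_log2_mean=11.0,
            baseline_log2_sd=0.5, sf_low=1.0, sf_high=1.0, seed=seed0 + i,
        )
        counts, samples, effects = gr.simulate_counts(cfg)
        counts.index = [f"{grade}_{g}" for g in counts.index]
        effects.index = counts.index
        counts_list.append(counts)
        for g, row in effects.iterrows():
            if abs(row["delta_N"]) > delta_cut:
                direction = "up" if row["delta_N"] > 0 else "down"
                truth[g] = f"{grade}-{direction}"
    return pd.concat(counts_list), samples, truth
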