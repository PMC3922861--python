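import numpy as np
import pandas as pd
import pytest

from regscreen.data import ExpressionDataset
from regscreen.pipeline import PipelineConfig, run_pipeline
from regscreen.simulate import SimulationConfig, simulate_experiment


def two_group_dataset(induced: dict, control: dict, substrate="avicel", time_h=6.0):
    """ExpressionDataset with one (substrate, time) contrast cell.

    ``induced``/``control`` map gene_id -> list of replicate values.
    """
    genes = list(induced)
    n_i = len(next(iter(induced.values())))
    n_c = len(next(iter(control.values())))
    cols, rows = [], []
    for r in range(n_i):
        cols.append(f"{substrate}_t{time_h:g}_r{r + 1}")
        rows.append((cols[-1], substrate, time_h, r + 1, "induced"))
    for r in range(n_c):
        cols.append(f"control_t{time_h:g}_r{r + 1}")
        rows.append((cols[-1], "control", time_h, r + 1, "control"))
    matrix = pd.DataFrame(
        [induced[g] + control[g] for g in genes],
        index=pd.Index(genes, name="gene_id"),
        columns=cols,
    )
    design = pd.DataFrame(
        rows, columns=["sample_id", "substrate", "time_h", "replicate", "role"]
    ).set_index("sample_id")
    return ExpressionDataset(matrix=matrix, design=design)


def null_dataset(n_genes, noise_sd, n_rep=4, seed=0):
    """Pure-noise one-contrast dataset for calibration checks."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(8.0, noise_sd, size=(n_genes, 2 * n_rep))
    genes = [f"g{i}" for i in range(n_genes)]
    induced = {g: vals[i, :n_rep].tolist() for i, g in enumerate(genes)}
    control = {g: vals[i, n_rep:].tolist() for i, g in enumerate(genes)}
    return two_group_dataset(induced, control)


@pytest.fixture(scope="session")
def tiny_zero_noise():
    """Zero-noise study: two clusters, effect 2.0, two planted regions."""
    cfg = SimulationConfig(
        n_genes=60,
        n_scaffolds=2,
        n_clusters=2,
        cluster_sizes=[15, 15],
        effect_log2=2.0,
        noise_sd=0.0,
        n_regions=2,
        region_span=5,
        n_regulators=2,
        rng_seed=7,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def screen_run(tmp_path_factory):
    """Full pipeline run on the default synthetic study (seed 1)."""
    outdir = tmp_path_factory.mktemp("screen") / "run"
    cfg = PipelineConfig(outdir=str(outdir), simulate={}, seed=1)
    return run_pipeline(cfg)
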