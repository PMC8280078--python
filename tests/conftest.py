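import pandas as pd
import pytest

from methrev import RunConfig, SimConfig, run_pipeline, simulate_dataset
from methrev.io import cov_col, meth_col


def make_tile(control_counts, experimental_counts, chrom="chr1", start=0,
              end=250):
    """Build a one-row tile table from (meth, cov) pairs per group."""
    row = {"chrom": chrom, "start": start, "end": end,
           "n_cpgs": 1, "genes": "G0000"}
    ctl = [f"ctl{i}" for i in range(len(control_counts))]
    exp = [f"exp{i}" for i in range(len(experimental_counts))]
    for s, (m, c) in zip(ctl, control_counts):
        row[meth_col(s)], row[cov_col(s)] = m, c
    for s, (m, c) in zip(exp, experimental_counts):
        row[meth_col(s)], row[cov_col(s)] = m, c
    return pd.DataFrame([row]), ctl, exp


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small synthetic dataset plus a completed pipeline run."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(n_genes=60, chrom_length=200_000, seed=1)
    genes, sites, tables, truth = simulate_dataset(cfg, out_dir=out)
    run_cfg = RunConfig(
        samples=cfg.sample_groups,
        coverage_files={s: str(out / f"{s}.cov.tsv") for s in cfg.samples},
        gene_table=str(out / "genes.bed"),
        out_dir=str(out / "results"),
        seed=cfg.seed,
    )
    bundle = run_pipeline(run_cfg)
    return {"cfg": cfg, "dir": out, "genes": genes, "sites": sites,
            "tables": tables, "truth": truth, "run_cfg": run_cfg,
            "bundle": bundle}
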