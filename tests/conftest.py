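import warnings

import pandas as pd
import pytest

from neutronet import PipelineConfig, default_design, run_pipeline, simulate_dataset
from neutronet import io as nio


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One default-design dataset (seed 11) run through the full pipeline."""
    root = tmp_path_factory.mktemp("dataset")
    design = default_design(seed=11)
    paths = simulate_dataset(design, root)
    cfg = PipelineConfig(paths={k: v for k, v in paths.items() if k != "ground_truth"},
                         outdir=str(root / "results"), seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline(cfg)
    truth = nio.read_json(paths["ground_truth"])
    return {"design": design, "paths": paths, "config": cfg,
            "manifest": manifest, "results": root / "results", "truth": truth}


@pytest.fixture()
def result_table(default_dataset):
    def load(name, **kw):
        return pd.read_csv(default_dataset["results"] / name, sep="\t", **kw)
    return load
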