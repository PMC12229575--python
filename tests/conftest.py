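import numpy as np
import pandas as pd
import pytest

from tcrdyn.simulate import SimConfig, simulate_cohort, write_bundle


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A scaled-down cohort: same structure, fast to generate."""
    kwargs = dict(
        cells_per_sample=150,
        n_clones=40,
        n_genes=120,
        n_tumor_clones=25,
        n_tumor_private=15,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(), include_counts=True)


@pytest.fixture(scope="session")
def small_bundle(small_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    write_bundle(small_cohort, outdir)
    return outdir


@pytest.fixture()
def toy_cells():
    """Hand-built 12-cell table: 1 patient, 2 timepoints, 2 subclusters."""
    rows = []
    for tp in ("baseline", "post_chemo"):
        for i in range(6):
            rows.append(
                {
                    "barcode": f"BC{i}",
                    "sample_id": f"P1_{tp}",
                    "patient_id": "P1",
                    "timepoint": tp,
                    "response": "RCB0_I",
                    "cell_type": "CD8_T",
                    "subcluster": "GZMB_early" if i < 4 else "naive_cm",
                }
            )
    return pd.DataFrame(rows)


def make_contigs(rows):
    return pd.DataFrame(
        rows,
        columns=["barcode", "sample_id", "chain", "cdr3_aa", "cdr3_nt", "productive", "umis"],
    )
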