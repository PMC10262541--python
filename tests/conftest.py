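import warnings

import numpy as np
import pandas as pd
import pytest

from holoshare import (
    AsvCountTable,
    SampleMetadata,
    SyntheticConfig,
    generate_herd,
)
from holoshare.filtering import (
    detect_kitome,
    filter_low_abundance_prevalence,
    filter_samples_min_reads,
    remove_asvs,
)


def make_meta(rows: dict) -> SampleMetadata:
    """Build metadata from {sample_id: (animal, site, time, group[, quarter])}."""
    recs = {}
    for sid, spec in rows.items():
        if spec == "control":
            recs[sid] = {
                "animal_id": pd.NA,
                "site": "control",
                "time": pd.NA,
                "group": pd.NA,
                "sm_score": np.nan,
                "bc_score": np.nan,
                "quarter": pd.NA,
                "is_control": True,
            }
        else:
            animal, site, time, group = spec[:4]
            recs[sid] = {
                "animal_id": animal,
                "site": site,
                "time": time,
                "group": group,
                "sm_score": 0.0,
                "bc_score": 0.0,
                "quarter": spec[4] if len(spec) > 4 else pd.NA,
                "is_control": False,
            }
    return SampleMetadata(pd.DataFrame.from_dict(recs, orient="index"))


@pytest.fixture(scope="session")
def small_herd():
    """A 10-animal herd with planted contaminants, cores and sharing."""
    cfg = SyntheticConfig(
        n_animals=10, pool_size=200, site_pool_size=60, seed=7
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_herd(cfg)


@pytest.fixture(scope="session")
def filtered_small_herd(small_herd):
    """The same herd after the full filtering chain."""
    table, meta, tree, truth = small_herd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t2, log = filter_low_abundance_prevalence(table, meta)
        kitome, _ = detect_kitome(t2, meta)
        t3, log = remove_asvs(t2, kitome, log)
        t4, log4 = filter_samples_min_reads(t3)
        log.extend(log4)
    return t4, meta, tree, truth, kitome, log


@pytest.fixture
def tiny_table():
    return AsvCountTable(
        ["s1", "s2", "s3"],
        ["a", "b", "c", "d"],
        [[5, 0, 1, 2], [0, 7, 0, 0], [1, 1, 1, 1]],
    )
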