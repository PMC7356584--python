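import numpy as np
import pandas as pd
import pytest

import cdscreen as cs
from cdscreen.curation import records_to_frame


@pytest.fixture(scope="session")
def planted_world():
    """Mid-size synthetic raw dataset with planted curation violations."""
    cfg = cs.SyntheticConfig(n_records=200, seed=11, signal_strength=1.0)
    raws, truth = cs.generate_raw_dataset(cfg)
    return cfg, raws, truth


@pytest.fixture(scope="session")
def curated_world(planted_world):
    cfg, raws, truth = planted_world
    records, report = cs.run_curation(raws)
    return cfg, records_to_frame(records), report, truth


@pytest.fixture(scope="session")
def labeled_world(curated_world):
    """Curated records featurized with the fast provider and labeled at 5.0."""
    cfg, df, report, truth = curated_world
    feat = cs.SystemFeaturizer(provider="minimal")
    X = feat.fit_transform(list(zip(df["guest_smiles"], df["cd_key"])))
    ds = cs.build_dataset(df, X, cs.ClassificationSpec(5.0))
    return df, feat, X, ds


def cyclodextrin_smiles(n: int) -> str:
    """Plain (non-stereo) SMILES of an unsubstituted cyclodextrin macrocycle."""
    def unit(i):
        d = i + 1
        if i == 0:
            return f"C91OC(CO)C(O{unit(1)})C(O)C1O"
        if i < n - 1:
            return f"C{d}OC(CO)C(O{unit(i + 1)})C(O)C{d}O"
        return f"C{d}OC(CO)C(O9)C(O)C{d}O"
    return unit(0)
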