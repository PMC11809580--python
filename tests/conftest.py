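import numpy as np
import pandas as pd
import pytest

from treestab.features import FEATURE_COLUMNS
from treestab.seqmodels import SubstModel
from treestab.synthdata import default_scenario_model, sample_tree, simulate_alignment
from treestab.treecore import parse_newick


@pytest.fixture
def jc():
    return SubstModel.jc69()


@pytest.fixture
def gtrg():
    return default_scenario_model()


@pytest.fixture
def quartet():
    return parse_newick("((A:0.1,B:0.2):0.15,(C:0.1,D:0.3):0.05);")


@pytest.fixture
def six_star():
    """Three cherries around a central node: ((A,B),(C,D),(E,F))."""
    return parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,(E:0.1,F:0.1):0.1);")


def random_tree_and_alignment(seed, n=8, L=400, model=None):
    rng = np.random.default_rng(seed)
    tree = sample_tree(n, rng)
    model = model or SubstModel.jc69()
    aln = simulate_alignment(tree, model, L, rng)
    return tree, aln


def synthetic_table(n=200, seed=0, frac_unstable=0.3):
    """A feature table whose label is a noisy threshold function of the
    dist_low_bootstrap_edge and distance_ratio_sd columns; everything else
    is noise.  Shared by the predictor tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.uniform(0, 1, (n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
    )
    score = (1 - df["dist_low_bootstrap_edge"]) + df["distance_ratio_sd"]
    cut = np.quantile(score, 1 - frac_unstable)
    df["unstable"] = ((score + rng.normal(0, 0.05, n)) > cut).astype(int)
    df["significant"] = df["unstable"] * (rng.random(n) < 0.7).astype(int)
    df["tii_norm"] = np.clip(
        df["unstable"] * (score - score.min()) / np.ptp(score)
        + rng.normal(0, 0.02, n),
        0, 1,
    )
    df["disruption_radius"] = df["tii_norm"]
    df["alignment"] = [f"a{i // 10}" for i in range(n)]
    return df
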