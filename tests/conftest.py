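import numpy as np
import pytest
from hypothesis import settings

from cslv import simulate as sim
from cslv.cohort import build_ukb_cohort
from cslv.features import partition_chromosomes, ukb_feature_table

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


TOY_SIZES = {"1": 10_000, "2": 8_000}


@pytest.fixture
def toy_partition():
    """Two toy chromosomes split into quarters."""
    return partition_chromosomes(TOY_SIZES, k=4)


@pytest.fixture(scope="session")
def strong_cohort():
    """Small end-to-end cohort under the strong-signal study conditions.

    800 people, 88 quarter-chromosome features rendered through the full
    l2r path; used wherever a learnable, distributed signal is needed.
    """
    config = sim.default_config(signal="strong", seed=11)
    truth = sim.calibrate_and_assign_labels(sim.simulate_true_offsets(config, n_persons=800))
    matrices = sim.render_l2r(truth)
    features = ukb_feature_table(list(matrices.values()), config.sizes)
    dataset = build_ukb_cohort(features, sim.render_phenotypes(truth))
    return truth, features, dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)
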