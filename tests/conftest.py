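import hypothesis
import pytest

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")

#: the worked-example pair used throughout the feature tests
EXAMPLE_PROTEIN = "DPPVPPPPPV"
EXAMPLE_RNA = "CCUCU"

CORE_CLAIM_SEEDS = tuple(range(20))
THRESHOLD_SEEDS = tuple(range(8))


@pytest.fixture(scope="session")
def example_pair():
    return EXAMPLE_PROTEIN, EXAMPLE_RNA


@pytest.fixture(scope="session")
def core_claim_trials():
    """Contamination and truth-scored CV results for the similarity-ranked
    vs random negative-selection study, one trial per seed."""
    from fire_pri.experiments import negative_quality_trial

    return [negative_quality_trial(seed=s) for s in CORE_CLAIM_SEEDS]


@pytest.fixture(scope="session")
def threshold_curves():
    """Cross-validated AUC curves over rising score-threshold targets."""
    from fire_pri.experiments import threshold_auc_curve

    return [threshold_auc_curve(seed=s) for s in THRESHOLD_SEEDS]


@pytest.fixture()
def toy_world():
    from fire_pri.synthetic_data import generate_world

    return generate_world(
        n_groups=3, proteins_per_group=4, n_rnas=10, mutation_rate=0.1,
        observation_fraction=0.6, seed=7,
    )
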