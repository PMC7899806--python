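import pytest

from ctoutcomes import FixtureSource, FixtureSpec, OutcomeSpec, generate_registry


def small_spec(seed: int = 7) -> FixtureSpec:
    """A 60-trial registry with four planted outcomes and two
    overlapping query terms."""
    return FixtureSpec(
        seed=seed,
        n_trials=60,
        outcomes=(
            OutcomeSpec("quality of life", "primary", 12),
            OutcomeSpec("forced expiratory volume in 1 second", "primary", 9),
            OutcomeSpec("six minute walk test", "secondary", 7),
            OutcomeSpec("dyspnea score", "other", 4),
        ),
        term_membership={"copd": 1.0, "emphysema": 0.4},
        fraction_without_outcomes=0.1,
        page_size=25,
    )


@pytest.fixture
def small_corpus(tmp_path):
    """(FixtureSource, GroundTruth, FixtureSpec) over a generated corpus."""
    spec = small_spec()
    truth = generate_registry(spec, tmp_path / "corpus")
    return FixtureSource(tmp_path / "corpus"), truth, spec
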