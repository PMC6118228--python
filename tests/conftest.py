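import numpy as np
import pytest

import lexitrain.learner as lrn
import lexitrain.lexicon as lex
import lexitrain.stimuli as stm
import lexitrain.trial as trl


@pytest.fixture(scope="session")
def lexicon():
    """A mid-sized synthetic lexicon shared across tests."""
    return lex.generate_lexicon(2500, seed=123, config=lex.LexiconConfig(zipf_tail_exponent=0.6))


@pytest.fixture(scope="session")
def candidates(lexicon):
    return lex.filter_training_candidates(lexicon)


@pytest.fixture(scope="session")
def listset(candidates):
    """A scaled-down matched list set: 40 triplets plus a 10-word core."""
    return stm.build_matched_triplets(candidates, n_triplets=40, seed=7, core_k=10)


@pytest.fixture()
def flat_learner():
    """Learner over ten words with uniform mid familiarity; no RT noise."""
    words = [f"w{i}" for i in range(10)]
    fam = np.full(10, 0.5)
    cfg = lrn.LearnerConfig(rt_noise_sd=0.0, rt_span_ms=0.0, rt_base_ms=600.0)
    return lrn.LearnerState(
        ability=0.0, words=words, familiarity=fam.copy(), baseline_familiarity=fam.copy(),
        config=cfg, seed=99,
    )


@pytest.fixture(scope="session")
def mini_trial_config():
    """Scaled-down trial configuration used by end-to-end tests."""
    cfg = trl.TrialConfig(
        n_participants=6,
        lexicon_n=2500,
        n_triplets=40,
        core_k=10,
        customized_m=30,
        test_k=20,
        test_core_k=6,
        customize="first",
        target_hours=2.0,
        fidelity="aggregate",
        include_followup=True,
    )
    return cfg


@pytest.fixture(scope="session")
def mini_materials(mini_trial_config):
    return trl.build_study_materials(mini_trial_config, seed=31)
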