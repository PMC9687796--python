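import numpy as np
import pytest

import siamvs as sv

# Small-but-realistic problem sizes keep the neural tests quick while
# preserving the architectures' structure (two conv/pool stages, dense
# head, measure fusion).
EASY_LENGTH = 128
SMALL_SMLP = sv.SmlpConfig(input_length=EASY_LENGTH, branch_width=128,
                           head_widths=(128, 64))
SMALL_SCNN = sv.Scnn1dConfig(input_length=EASY_LENGTH, n_filters=8,
                             feature_width=32)


@pytest.fixture(scope="session")
def easy_library() -> sv.ScreeningLibrary:
    """Two well-separated activity classes over a background pool.

    Within-class target similarity 0.6 against a sparse background, the
    easy regime in which a pair scorer must learn to separate same-class
    from different-class pairs.
    """
    cfg = sv.GeneratorConfig(
        (sv.ClassSpec("A", 60, 0.6), sv.ClassSpec("B", 60, 0.6)),
        n_inactive=120,
        length=EASY_LENGTH,
        density=0.08,
        seed=11,
    )
    return sv.generate_library(cfg)


@pytest.fixture(scope="session")
def easy_pairs(easy_library) -> sv.PairBatch:
    return sv.generate_pairs(easy_library, 600, pos_fraction=0.5, seed=2)


@pytest.fixture(scope="session")
def heldout_pairs(easy_library) -> sv.PairBatch:
    return sv.generate_pairs(easy_library, 300, pos_fraction=0.5, seed=99)


@pytest.fixture(scope="session")
def trained_smlp2(easy_pairs) -> sv.SmlpScorer:
    """An SMLP scorer (two measures) trained on the easy configuration."""
    scorer = sv.SmlpScorer(SMALL_SMLP, seed=0)
    scorer.fit(easy_pairs, sv.TrainSpec(epochs=8, batch_size=32, seed=0))
    return scorer


@pytest.fixture(scope="session")
def trained_scnn2(easy_pairs) -> sv.Scnn1dScorer:
    scorer = sv.Scnn1dScorer(SMALL_SCNN, seed=0)
    scorer.fit(easy_pairs, sv.TrainSpec(epochs=4, batch_size=32, seed=0))
    return scorer


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
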