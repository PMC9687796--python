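import numpy as np
import pytest

import siamvs as sv
from siamvs._autodiff import Tensor


SMALL_HYBRID = sv.FeatureHybridConfig(
    combine="sum", input_length=128, smlp_branch_width=64,
    smlp_head_widths=(64, 32), n_filters=8, feature_width=32,
)


def random_fp(rng, length=128):
    v = rng.integers(0, 4, size=length)
    v[rng.integers(length)] += 1
    return v


class TestDecisionFusion:
    def test_score_is_exact_max_of_components(self, trained_smlp2,
                                              trained_scnn2, rng):
        hybrid = sv.DecisionHybridScorer(trained_smlp2, trained_scnn2)
        A = np.stack([random_fp(rng) for _ in range(50)])
        B = np.stack([random_fp(rng) for _ in range(50)])
        fused = hybrid.score_pairs(A, B)
        sa = trained_smlp2.score_pairs(A, B)
        sb = trained_scnn2.score_pairs(A, B)
        assert np.array_equal(fused, np.maximum(sa, sb))

    def test_fused_dominates_components_on_many_pairs(self, trained_smlp2,
                                                      trained_scnn2,
                                                      easy_library, rng):
        hybrid = sv.DecisionHybridScorer(trained_smlp2, trained_scnn2)
        idx = rng.integers(easy_library.n_molecules, size=(1000, 2))
        A = easy_library.fingerprints[idx[:, 0]]
        B = easy_library.fingerprints[idx[:, 1]]
        fused = hybrid.score_pairs(A, B)
        assert (fused >= trained_smlp2.score_pairs(A, B) - 1e-15).all()
        assert (fused >= trained_scnn2.score_pairs(A, B) - 1e-15).all()

    def test_equal_components_pass_through(self, trained_smlp2, rng):
        hybrid = sv.DecisionHybridScorer(trained_smlp2, trained_smlp2)
        a, b = random_fp(rng), random_fp(rng)
        assert sv.decision_fuse_max(hybrid, a, b) == trained_smlp2.score_pair(a, b)

    def test_untrained_components_rejected(self):
        fresh = sv.SmlpScorer(
            sv.SmlpConfig(input_length=64, branch_width=16, head_widths=(16,)),
            seed=0,
        )
        with pytest.raises(ValueError, match="trained"):
            sv.DecisionHybridScorer(fresh, fresh)

    def test_trainable_hybrid_requires_fit_before_scoring(self, easy_pairs):
        hybrid = sv.TrainableDecisionHybrid(
            sv.SmlpScorer(sv.SmlpConfig(input_length=128, branch_width=32,
                                        head_widths=(32,)), seed=0),
            sv.Scnn1dScorer(sv.Scnn1dConfig(input_length=128, n_filters=4,
                                            feature_width=16), seed=1),
        )
        with pytest.raises(ValueError, match="before training"):
            hybrid.score_pairs(easy_pairs.a[:2], easy_pairs.b[:2])
        small = sv.PairBatch(easy_pairs.a[:40], easy_pairs.b[:40],
                             easy_pairs.labels[:40])
        trace = hybrid.fit(small, sv.TrainSpec(epochs=1, batch_size=8))
        assert hybrid.trained and len(trace) == 2  # one epoch per component


class TestFeatureFusion:
    @pytest.mark.parametrize("combine", ["sum", "max"])
    def test_scores_bounded_and_symmetric(self, combine, rng):
        scorer = sv.build_feature_hybrid(
            combine, seed=4,
            cfg=sv.FeatureHybridConfig(
                combine=combine, input_length=128, smlp_branch_width=64,
                smlp_head_widths=(64, 32), n_filters=8, feature_width=32),
        )
        for _ in range(10):
            a, b = random_fp(rng), random_fp(rng)
            s = scorer.score_pair(a, b)
            assert 0.0 <= s <= 1.0
            assert s == pytest.approx(scorer.score_pair(b, a), abs=1e-6)

    def test_invalid_combine_token_rejected(self):
        with pytest.raises(ValueError, match="sum.*max|combine"):
            sv.build_feature_hybrid("mean")

    def test_sum_and_max_agree_on_equal_trunks(self, rng, monkeypatch):
        """Elementwise sum and max of two equal 512-vectors feed the head
        with 2v vs v; with identical head weights the designs agree once
        both trunks emit the same vector and the head halves the sum."""
        cfg_sum = SMALL_HYBRID
        cfg_max = sv.FeatureHybridConfig(**{**cfg_sum.__dict__, "combine": "max"})
        s_sum = sv.FeatureHybridScorer(cfg_sum, seed=7)
        s_max = sv.FeatureHybridScorer(cfg_max, seed=7)  # same init
        # force both trunks of each model to the same vector
        shared = np.abs(np.random.default_rng(0).normal(size=(1, 32)))

        def fake_trunk(self, xa, xb):
            return Tensor(shared)

        monkeypatch.setattr(sv.FeatureHybridScorer, "_smlp_trunk", fake_trunk)
        monkeypatch.setattr(sv.FeatureHybridScorer, "_scnn_trunk", fake_trunk)
        a, b = random_fp(rng), random_fp(rng)
        # sum combines to 2*shared; halve its head weights to compare
        s_sum.params["Wo"].data *= 0.5
        s_sum.params["bo"].data[:] = s_max.params["bo"].data
        assert s_sum.score_pair(a, b) == pytest.approx(
            s_max.score_pair(a, b), abs=1e-12
        )

    def test_zeroed_trunk_ablation_identity(self, rng, monkeypatch):
        """With combine=sum and one trunk forced to zero, the hybrid equals
        the head applied to the other trunk alone."""
        scorer = sv.FeatureHybridScorer(SMALL_HYBRID, seed=9)
        a, b = random_fp(rng), random_fp(rng)

        def zero_trunk(self, xa, xb):
            return Tensor(np.zeros((1, 32)))

        monkeypatch.setattr(sv.FeatureHybridScorer, "_scnn_trunk", zero_trunk)
        hybrid_score = scorer.score_pair(a, b)
        va = scorer._smlp_trunk(
            Tensor(a.astype(float)[None]), Tensor(b.astype(float)[None])
        )
        from siamvs.siamese_models import _dense

        head_only = _dense(
            va, scorer.params["Wo"], scorer.params["bo"]
        ).sigmoid().data.item()
        assert hybrid_score == pytest.approx(head_only, abs=1e-12)

    def test_training_decreases_loss_and_is_deterministic(self, easy_pairs):
        probe_a, probe_b = easy_pairs.a[0], easy_pairs.b[1]
        finals = []
        for _ in range(2):
            scorer = sv.build_feature_hybrid("max", seed=2, cfg=sv.FeatureHybridConfig(
                combine="max", input_length=128, smlp_branch_width=64,
                smlp_head_widths=(64, 32), n_filters=8, feature_width=32))
            trace = sv.train_feature_hybrid(
                scorer,
                sv.PairBatch(easy_pairs.a[:200], easy_pairs.b[:200],
                             easy_pairs.labels[:200]),
                sv.TrainSpec(epochs=3, batch_size=32, seed=2),
            )
            assert len(trace) == 3 and np.isfinite(trace).all()
            assert trace[-1] < trace[0]
            finals.append(scorer.score_pair(probe_a, probe_b))
        assert finals[0] == finals[1]

    def test_trunk_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            sv.FeatureHybridConfig(combine="sum", smlp_head_widths=(1024, 256))
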