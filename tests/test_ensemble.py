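import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hergml.alerts import default_alerts
from hergml.chemio import Call, ConfigurationError, InputError, Prediction
from hergml.ensemble import (
    SourceRatio,
    combine_fallback,
    combine_most_confident,
    full_stack_predict,
    weighted_training_set,
)
from hergml.rf_model import RfConfig, RfModel
from hergml.sohn import SohnConfig, SohnModel


def pred(call, confidence, model="m", rid="q"):
    return Prediction(rid, call, confidence, model)


class TestSourceRatio:
    def test_parse(self):
        ratio = SourceRatio.parse("2:5")
        assert (ratio.public_weight, ratio.private_weight) == (2.0, 5.0)
        assert str(ratio) == "2:5"

    def test_both_zero_rejected(self):
        with pytest.raises(ConfigurationError):
            SourceRatio(0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ConfigurationError):
            SourceRatio(-1, 5)


class TestWeightedTrainingSet:
    def test_effective_weight_ratio_respects_source_sizes(self, small_dataset):
        public = small_dataset.public[:100]
        private = small_dataset.private_train[:50]
        records, weights = weighted_training_set(public, private, SourceRatio(1, 1))
        assert len(records) == 150
        w_pub, w_priv = weights[0], weights[-1]
        # each private record carries twice a public record's weight
        assert w_priv == pytest.approx(2 * w_pub)
        total_pub = weights[: len(public)].sum()
        total_priv = weights[len(public):].sum()
        assert total_pub == pytest.approx(total_priv)
        assert weights.mean() == pytest.approx(1.0)

    @pytest.mark.parametrize("text", ["5:0", "0:5"])
    def test_single_source_ratio_drops_the_other_source(self, small_dataset, text):
        records, weights = weighted_training_set(
            small_dataset.public, small_dataset.private_train, SourceRatio.parse(text)
        )
        expected = small_dataset.public if text == "5:0" else small_dataset.private_train
        assert records == list(expected)
        assert weights is None

    def test_ratio_extremes_reproduce_single_source_models_bit_for_bit(self, small_dataset):
        probe = small_dataset.private_test[:15]
        cfg = RfConfig(n_estimators=50, seed=3)
        for text, source in (("5:0", small_dataset.public), ("0:5", small_dataset.private_train)):
            records, weights = weighted_training_set(
                small_dataset.public, small_dataset.private_train, SourceRatio.parse(text)
            )
            via_ratio = RfModel(cfg).fit(records, sample_weight=weights).predict(probe)
            direct = RfModel(cfg).fit(list(source)).predict(probe)
            assert [(p.call, p.confidence) for p in via_ratio] == [
                (p.call, p.confidence) for p in direct
            ]
            sohn_ratio = SohnModel(SohnConfig(seed=3)).fit(records, sample_weight=weights)
            sohn_direct = SohnModel(SohnConfig(seed=3)).fit(list(source))
            assert [(p.call, p.confidence) for p in sohn_ratio.predict(probe)] == [
                (p.call, p.confidence) for p in sohn_direct.predict(probe)
            ]

    def test_mixed_ratio_with_empty_source_rejected(self, small_dataset):
        with pytest.raises(InputError):
            weighted_training_set([], small_dataset.private_train, SourceRatio(1, 1))


class TestFallback:
    def test_low_confidence_defers_to_expert(self):
        stat = pred(Call.INACTIVE, 0.65, "rf")
        expert = pred(Call.ACTIVE, None, "expert")
        combined = combine_fallback(stat, expert, tau=0.7)
        assert combined.call is Call.ACTIVE
        assert "fallback" in combined.provenance

    def test_confident_statistical_call_wins(self):
        stat = pred(Call.ACTIVE, 0.9, "rf")
        combined = combine_fallback(stat, pred(Call.INACTIVE, None, "expert"), tau=0.7)
        assert combined is stat

    def test_tau_zero_is_identity_on_the_statistical_model(self):
        for confidence in (0.0, 0.2, 0.99):
            stat = pred(Call.INACTIVE, confidence, "rf")
            assert combine_fallback(stat, pred(Call.ACTIVE, None, "expert"), tau=0.0) is stat

    def test_tau_above_one_always_uses_the_expert(self):
        stat = pred(Call.INACTIVE, 1.0, "rf")
        combined = combine_fallback(stat, pred(Call.ACTIVE, None, "expert"), tau=1.01)
        assert combined.call is Call.ACTIVE

    def test_non_numeric_statistical_confidence_rejected(self):
        with pytest.raises(InputError):
            combine_fallback(pred(Call.ACTIVE, None, "expert"), pred(Call.ACTIVE, None), 0.5)


class TestMostConfident:
    def test_highest_confidence_wins(self):
        chosen = combine_most_confident(
            [pred(Call.ACTIVE, 0.9, "a"), pred(Call.INACTIVE, 0.6, "b")]
        )
        assert (chosen.call, chosen.confidence) == (Call.ACTIVE, 0.9)

    def test_single_prediction_is_returned_verbatim(self):
        only = pred(Call.INACTIVE, 0.4)
        assert combine_most_confident([only]) is only

    def test_conflicting_tie_resolves_to_active(self):
        chosen = combine_most_confident(
            [pred(Call.ACTIVE, 0.7, "a"), pred(Call.INACTIVE, 0.7, "b")]
        )
        assert chosen.call is Call.ACTIVE

    def test_predictions_without_confidence_are_ignored(self):
        chosen = combine_most_confident(
            [pred(Call.ACTIVE, None, "expert"), pred(Call.INACTIVE, 0.5, "rf")]
        )
        assert chosen.call is Call.INACTIVE

    def test_no_numeric_confidence_rejected(self):
        with pytest.raises(InputError):
            combine_most_confident([pred(Call.ACTIVE, None, "expert")])

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([Call.ACTIVE, Call.INACTIVE]),
                st.floats(0, 1, allow_nan=False),
            ),
            min_size=1,
            max_size=6,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant(self, entries, rnd):
        preds = [pred(c, conf, model=f"m{i}") for i, (c, conf) in enumerate(entries)]
        shuffled = list(preds)
        rnd.shuffle(shuffled)
        a = combine_most_confident(preds)
        b = combine_most_confident(shuffled)
        assert (a.call, a.confidence, a.model) == (b.call, b.confidence, b.model)


@pytest.fixture(scope="module")
def models(small_dataset):
    train = small_dataset.private_train
    rf = RfModel(RfConfig(n_estimators=50, seed=0)).fit(train)
    sohn = SohnModel(SohnConfig(seed=0)).fit(train)
    return sohn, rf


class TestFullStack:

    def test_confident_consensus_ignores_the_expert(self, models, small_dataset):
        sohn, rf = models
        query = small_dataset.private_train[0]  # exact training match: confidence 1
        combined = full_stack_predict(sohn, rf, default_alerts(), query, tau=0.7)
        stat = combine_most_confident(
            [sohn.predict_record(query), rf.predict_record(query)]
        )
        assert combined.call is stat.call

    def test_tau_above_one_degenerates_to_the_expert(self, models, small_dataset):
        sohn, rf = models
        alerts = default_alerts()
        from hergml.alerts import expert_predict

        for query in small_dataset.private_test[:10]:
            combined = full_stack_predict(sohn, rf, alerts, query, tau=1.01)
            assert combined.call is expert_predict(alerts, query).call
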