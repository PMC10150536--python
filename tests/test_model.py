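"""The error model: encoding, network behaviour, rescaling, prediction."""

import numpy as np
import pandas as pd
import pytest

from plasmavar.features import TRINUCLEOTIDES, FeatureSchema, SchemaError
from plasmavar.model import (
    ALLELE_INDEX,
    ErrorModelArtifact,
    build_network,
    predict_error_rates,
    rescale_probabilities,
    train_error_model,
)
from plasmavar.nn import TrainConfig
from plasmavar.simulate import simulate_training_table


def small_schema():
    df = pd.DataFrame({
        "read_position": [1, 2, 3, 4],
        "fragment_size": [160.0, 170.0, 340.0, 150.0],
        "strand": ["forward", "reverse", "forward", "reverse"],
        "first_in_pair": [True, False, True, False],
        "trinucleotide": ["ACG", "TTT", "GGA", "CAT"],
    })
    return FeatureSchema.from_table(
        df, numeric=["read_position", "fragment_size"],
        categorical=["strand", "first_in_pair"])


class TestFeatureSchema:
    def test_input_width_arithmetic(self):
        schema = small_schema()
        # 2 numeric + 2 one-hot + 2 one-hot + 3 embedding dims
        assert schema.dense_width == 6
        assert schema.input_width == 9

    def test_vocabulary_covers_all_trinucleotides(self):
        assert len(TRINUCLEOTIDES) == 64
        assert len(set(TRINUCLEOTIDES)) == 64

    def test_duplicate_feature_rejected(self):
        with pytest.raises(SchemaError):
            FeatureSchema(numeric=["x"], numeric_stats={"x": (0, 1)},
                          categorical={"x": [0, 1]})

    def test_empty_schema_rejected(self):
        with pytest.raises(SchemaError):
            FeatureSchema(numeric=[], numeric_stats={}, categorical={},
                          embed_trinucleotide=False)

    def test_drop_trinucleotide_substitutes_ref_base(self):
        schema = small_schema().drop("trinucleotide")
        assert not schema.embed_trinucleotide
        assert schema.categorical["ref_base"] == ["A", "C", "G", "T"]

    def test_roundtrip_serialisation(self):
        schema = small_schema()
        again = FeatureSchema.from_dict(schema.to_dict())
        assert again.numeric == schema.numeric
        assert again.numeric_stats == schema.numeric_stats


class TestNetwork:
    def test_output_is_a_probability_simplex(self):
        schema = small_schema()
        net = build_network(schema, hidden_layout=(16, 8), seed=0)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, schema.dense_width))
        tnc = rng.integers(0, 64, 50)
        p = net.forward(X, tnc)
        assert p.shape == (50, 4)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_weights(self):
        table = simulate_training_table(n_positions=40_000, rate_fn=5e-3,
                                        beta=0.05, seed=2)
        cfg = TrainConfig(hidden_layout=(16, 8), max_epochs=3)
        a = train_error_model(table, config=cfg, seed=9)
        b = train_error_model(table, config=cfg, seed=9)
        for k, w in a.model.get_weights().items():
            np.testing.assert_array_equal(w, b.model.get_weights()[k])

    def test_training_reduces_nll(self):
        table = simulate_training_table(n_positions=60_000, rate_fn=5e-3,
                                        beta=0.05, seed=3)
        art = train_error_model(
            table, config=TrainConfig(hidden_layout=(32, 16), max_epochs=10),
            seed=3)
        meta = art.training_meta
        assert meta["final_val_nll"] <= meta["initial_nll"]


class TestRescaling:
    def test_beta_one_is_identity(self):
        p = np.array([[0.7, 0.1, 0.1, 0.1]])
        np.testing.assert_allclose(rescale_probabilities(p, "A", 1.0), p)

    def test_printed_conditional_rate_example(self):
        """(A,C,G,T) = (0.98, 0.01, 0.005, 0.005), ref A, alt C:
        e(R->M) = 0.01 / 0.99."""
        p = np.array([0.98, 0.01, 0.005, 0.005])
        e = p[1] / (p[0] + p[1])
        assert e == pytest.approx(0.0101010101, abs=1e-8)

    def test_zero_alt_probability_gives_zero_rate(self):
        p = np.array([[1.0, 0.0, 0.0, 0.0]])
        r = rescale_probabilities(p, "A", 0.5)
        assert r[0, 1] / (r[0, 0] + r[0, 1]) == 0.0

    def test_invalid_beta_refused(self):
        with pytest.raises(ValueError):
            rescale_probabilities(np.ones((1, 4)) / 4, "A", 0.0)
        with pytest.raises(ValueError):
            rescale_probabilities(np.ones((1, 4)) / 4, "A", 1.5)

    def test_rescaling_undoes_downsampling_prior_shift(self):
        # analytic check: downsampling matches by beta turns p into
        # p' ~ (beta*p_ref, p_others); rescaling must invert that.
        p_true = np.array([0.996, 0.002, 0.001, 0.001])
        beta = 0.01
        down = p_true * np.array([beta, 1, 1, 1])
        down /= down.sum()
        np.testing.assert_allclose(
            rescale_probabilities(down[None, :], "A", beta)[0], p_true,
            atol=1e-12)


class TestPrediction:
    def test_error_rate_pairs(self, const_rate_artifact):
        test = simulate_training_table(n_positions=3000, rate_fn=1e-3,
                                       beta=1.0, seed=77)
        df = test.df.head(100).copy()
        df["trinucleotide"] = "AAA"
        e_rm, e_mr = predict_error_rates(const_rate_artifact, df, "A", "C")
        assert np.all((e_rm >= 0) & (e_rm < 1))
        assert np.all((e_mr >= 0) & (e_mr < 1))
        # constant-rate generator: both directions should be near 1e-3
        assert abs(np.log10(e_rm.mean()) - (-3)) < 0.5

    def test_identical_alleles_rejected(self, const_rate_artifact):
        df = simulate_training_table(n_positions=100, beta=1.0, seed=1).df
        with pytest.raises(ValueError):
            predict_error_rates(const_rate_artifact, df, "A", "A")

    def test_artifact_roundtrip(self, const_rate_artifact, tmp_path):
        path = tmp_path / "model.pvar"
        const_rate_artifact.save(path)
        again = ErrorModelArtifact.load(path)
        test = simulate_training_table(n_positions=500, beta=1.0, seed=8).df
        np.testing.assert_allclose(again.predict_raw(test),
                                   const_rate_artifact.predict_raw(test))
        assert again.beta == const_rate_artifact.beta


class TestEmbedding:
    def test_contexts_with_shared_error_behaviour_cluster(self):
        """Contexts given identical synthetic error rates end up closer in
        embedding space (median pairwise distance) than contexts whose
        rates differ tenfold."""
        from plasmavar.features import TRINUCLEOTIDES, TNC_INDEX

        def rate_fn(df):
            hot = df["trinucleotide"].str.startswith("A").to_numpy()
            return np.where(hot, 1e-2, 1e-3)

        table = simulate_training_table(n_positions=1_500_000,
                                        rate_fn=rate_fn, beta=0.02, seed=41)
        art = train_error_model(
            table, config=TrainConfig(max_epochs=60, patience=6), seed=41)
        E = art.model.E
        hot = [TNC_INDEX[t] for t in TRINUCLEOTIDES if t.startswith("A")]
        cold = [TNC_INDEX[t] for t in TRINUCLEOTIDES if not t.startswith("A")]
        rng = np.random.default_rng(0)

        def med_dist(ids_a, ids_b, n=400):
            i = rng.choice(ids_a, n)
            j = rng.choice(ids_b, n)
            keep = i != j
            return np.median(np.linalg.norm(E[i[keep]] - E[j[keep]], axis=1))

        within = min(med_dist(hot, hot), med_dist(cold, cold))
        across = med_dist(hot, cold)
        assert within < across


class TestCalibration:
    def test_recovers_base_rate_after_rescaling(self, const_rate_artifact):
        """Trained on beta=0.01 downsampled data with true rate 1e-3, the
        rescaled mean mismatch probability on held-out data is within 10%."""
        test = simulate_training_table(n_positions=50_000, rate_fn=1e-3,
                                       beta=1.0, seed=99)
        pr = rescale_probabilities(
            const_rate_artifact.predict_raw(test.df),
            test.df["ref_allele"].to_numpy(), const_rate_artifact.beta)
        ridx = test.df["ref_allele"].map(ALLELE_INDEX).to_numpy()
        mm = 1 - pr[np.arange(len(pr)), ridx]
        assert abs(mm.mean() / 1e-3 - 1) < 0.10

    def test_binned_calibration_slope(self, calibration_slope):
        """Feature-dependent rates spanning ~1e-4..1e-2: regressing binned
        empirical mismatch rates on predicted rates gives slope 1 +/- 0.15."""
        assert abs(calibration_slope - 1) < 0.15
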