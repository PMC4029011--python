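"""Generator invariants: simplex membership, determinism, believability tilt,
derived probabilities, and the dual-source response mechanism."""

import numpy as np
import pytest

from probreason import (
    JointDistribution,
    SyntheticConfig,
    derive_estimates,
    generate_dataset,
    sample_joint,
)
from probreason.synthetic import ConfigError, DegenerateJointError
from probreason.dataset_io import MINOR_EVENT


class TestSampleJoint:
    def test_cells_live_on_the_simplex(self):
        rng = np.random.default_rng(0)
        config = SyntheticConfig(joint_prior_weights=(1, 1, 1, 1), believability_boost=0.0)
        for _ in range(100):
            joint = sample_joint(rng, config)
            assert all(0.0 <= c <= 1.0 for c in joint.cells)
            assert sum(joint.cells) == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_same_cells(self):
        config = SyntheticConfig(seed=4)
        a = sample_joint(np.random.default_rng(4), config)
        b = sample_joint(np.random.default_rng(4), config)
        assert a == b

    def test_boost_tilts_q_given_p_above_q_given_notp(self):
        # Monte-Carlo check of the tilt mechanism at boost 5
        rng = np.random.default_rng(1)
        config = SyntheticConfig(
            joint_prior_weights=(1, 1, 1, 1), believability_boost=5.0
        )
        qp, qnp = [], []
        for _ in range(1000):
            est = derive_estimates(sample_joint(rng, config))
            qp.append(est["q_given_p"])
            qnp.append(est["q_given_notp"])
        assert np.mean(qp) > np.mean(qnp)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ConfigError, match="positive"):
            SyntheticConfig(joint_prior_weights=(1.0, 0.0, 1.0, 1.0))


class TestDeriveEstimates:
    def test_cell_sum_oracle(self):
        est = derive_estimates(JointDistribution(0.4, 0.1, 0.2, 0.3))
        assert est["q_given_p"] == pytest.approx(0.8)
        assert est["q_given_notp"] == pytest.approx(0.4)
        assert est["conj"] == pytest.approx(0.4)
        assert est["material"] == pytest.approx(0.9)
        assert est["q"] == pytest.approx(0.6)

    def test_no_p_and_notq_mass_gives_certain_conditional(self):
        est = derive_estimates(JointDistribution(0.5, 0.0, 0.0, 0.5))
        assert est["q_given_p"] == 1.0
        assert est["material"] == 1.0

    def test_uniform_joint_is_symmetric(self):
        est = derive_estimates(JointDistribution(0.25, 0.25, 0.25, 0.25))
        assert est["q_given_p"] == est["q_given_notp"] == 0.5

    def test_zero_marginal_raises(self):
        with pytest.raises(DegenerateJointError):
            derive_estimates(JointDistribution(0.0, 0.0, 0.5, 0.5))


class TestGenerateDataset:
    def test_same_config_same_dataset(self):
        config = SyntheticConfig(n_participants=30, seed=7)
        a, truth_a = generate_dataset(config)
        b, truth_b = generate_dataset(config)
        assert a == b
        assert truth_a.equals(truth_b)

    def test_noisy_responses_are_integer_raw_in_bounds(self):
        dataset, _ = generate_dataset(SyntheticConfig(n_participants=5, seed=2))
        for rec in dataset.inference_records:
            for est in rec.estimates.values():
                assert 0.0 <= est.raw <= 100.0
                assert est.raw == round(est.raw)
                assert 0.0 <= est.value <= 1.0

    def test_lambda_zero_noiseless_conclusion_equals_xi(self):
        config = SyntheticConfig(
            n_participants=10, noise_sd=0.0, lambda_dist=("point", 0.0), seed=9
        )
        dataset, truth = generate_dataset(config)
        xi = truth.set_index(["participant_id", "conditional_id"])["xi"]
        for rec in dataset.inference_records:
            assert rec.response == pytest.approx(
                xi[(rec.participant_id, rec.conditional_id)], abs=1e-12
            )

    def test_lambda_one_tau_one_forces_certain_conclusion(self):
        config = SyntheticConfig(
            n_participants=5,
            noise_sd=0.0,
            lambda_dist=("point", 1.0),
            tau_profile={"MP": 1.0, "MT": 1.0, "AC": 1.0, "DA": 1.0},
            seed=9,
        )
        dataset, _ = generate_dataset(config)
        assert all(rec.response == pytest.approx(1.0) for rec in dataset.inference_records)

    def test_truth_sidecar_aligns_with_records(self, noisy_dataset):
        dataset, truth = noisy_dataset
        keys = {(r.participant_id, r.conditional_id, r.inference)
                for r in dataset.inference_records}
        truth_keys = set(
            truth[["participant_id", "conditional_id", "inference"]].itertuples(index=False)
        )
        assert keys == truth_keys
        # lambda is a participant-level latent: constant within participant
        assert (truth.groupby("participant_id")["lambda"].nunique() == 1).all()

    def test_event_item_is_conclusion_marginal(self):
        # with no noise the event item equals the latent conclusion marginal,
        # which for lambda=0 equals the conclusion response
        config = SyntheticConfig(
            n_participants=5, noise_sd=0.0, lambda_dist=("point", 0.0), seed=12
        )
        dataset, _ = generate_dataset(config)
        for rec in dataset.inference_records:
            assert rec.value("event") == pytest.approx(rec.response, abs=1e-12)
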