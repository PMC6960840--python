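import math

import numpy as np
import pytest

from ddsr import synthetic
from ddsr.diverse_density import (
    Bag,
    BagSpec,
    dd_value,
    instance_prob,
    learn_dictionary,
    log_dd,
    make_bags,
    maximize_dd,
    negative_bag_prob,
    positive_bag_prob,
)


def brute_force_dd(bags, t):
    """Independent linear-domain evaluation of the DD product."""
    t = np.asarray(t, dtype=float)
    value = 1.0
    for bag in bags:
        probs = [math.exp(-float(np.sum((inst - t) ** 2))) for inst in bag.instances]
        if bag.polarity == "positive":
            q = 1.0
            for p in probs:
                q *= 1.0 - p
            value *= 1.0 - q
        else:
            for p in probs:
                value *= 1.0 - p
    return value


@pytest.mark.parametrize("instance, t, expected", [
    ([0.0], [0.0], 1.0),
    ([0.0], [1.0], math.exp(-1.0)),
    ([0.0, 0.0], [1.0, 1.0], math.exp(-2.0)),
])
def test_instance_prob_closed_forms(instance, t, expected):
    assert instance_prob(np.array(instance), np.array(t)) == pytest.approx(expected, rel=1e-12)


def test_instance_prob_length_mismatch():
    with pytest.raises(ValueError):
        instance_prob(np.zeros(3), np.zeros(4))


class TestBagProbs:
    def test_positive_bag_absorbs_member(self):
        t = np.array([0.0])
        bag = Bag(instances=np.array([[0.0], [2.0]]), polarity="positive")
        assert positive_bag_prob(bag, t) == pytest.approx(1.0, abs=1e-15)

    def test_positive_bag_far_limit(self):
        bag = Bag(instances=np.array([[6.0], [7.0]]), polarity="positive")
        assert positive_bag_prob(bag, np.array([0.0])) < 1e-12

    def test_negative_bag_member_forces_zero(self):
        bag = Bag(instances=np.array([[0.0], [5.0]]), polarity="negative")
        assert negative_bag_prob(bag, np.array([0.0])) == 0.0

    def test_negative_bag_closed_form(self):
        bag = Bag(instances=np.array([[1.0]]), polarity="negative")
        assert negative_bag_prob(bag, np.array([0.0])) == pytest.approx(
            1.0 - math.exp(-1.0), rel=1e-12)

    def test_negative_bag_far_limit(self):
        bag = Bag(instances=np.array([[10.0]]), polarity="negative")
        assert negative_bag_prob(bag, np.array([0.0])) == pytest.approx(1.0, rel=1e-12)

    def test_polarity_checked(self):
        bag = Bag(instances=np.array([[0.0]]), polarity="negative")
        with pytest.raises(ValueError):
            positive_bag_prob(bag, np.array([0.0]))


class TestDdValue:
    def test_single_positive_bag_containing_t(self):
        bags = [Bag(instances=np.array([[1.0, 2.0]]), polarity="positive")]
        dd, ld = dd_value(bags, np.array([1.0, 2.0]))
        assert dd == 1.0
        assert ld == 0.0

    def test_negative_bag_containing_t_zeroes_dd(self):
        bags = [
            Bag(instances=np.array([[0.0]]), polarity="positive"),
            Bag(instances=np.array([[0.0]]), polarity="negative"),
        ]
        dd, ld = dd_value(bags, np.array([0.0]))
        assert dd == 0.0
        assert ld == -np.inf

    def test_requires_positive_bag(self):
        with pytest.raises(ValueError):
            dd_value([Bag(instances=np.array([[0.0]]), polarity="negative")],
                     np.array([0.0]))

    def test_matches_direct_product_oracle(self):
        bags = [
            Bag(instances=np.array([[0.0], [5.0]]), polarity="positive"),
            Bag(instances=np.array([[0.1]]), polarity="positive"),
            Bag(instances=np.array([[3.0]]), polarity="negative"),
        ]
        t = np.array([0.05])
        dd, _ = dd_value(bags, t)
        assert dd == pytest.approx(brute_force_dd(bags, t), rel=1e-12)

    def test_log_and_linear_domains_agree(self, rng):
        for _ in range(50):
            bags = [Bag(instances=rng.normal(size=(3, 4)),
                        polarity="positive" if rng.random() < 0.6 else "negative")
                    for _ in range(5)]
            if not any(b.polarity == "positive" for b in bags):
                bags[0].polarity = "positive"
            t = rng.normal(size=4)
            dd, ld = dd_value(bags, t)
            if dd > 1e-300:
                assert ld == pytest.approx(math.log(dd), rel=1e-10)

    def test_adding_negative_bag_never_increases_dd(self, rng):
        for _ in range(200):
            bags = [Bag(instances=rng.normal(size=(2, 3)), polarity="positive")]
            t = rng.normal(size=3)
            before = log_dd(bags, t)
            bags.append(Bag(instances=rng.normal(size=(2, 3)), polarity="negative"))
            assert log_dd(bags, t) <= before


class TestMaximizeDd:
    def test_single_instance_degenerate(self):
        bag = Bag(instances=np.array([[1.0, 1.0]]), polarity="positive")
        concept = maximize_dd([bag])
        np.testing.assert_array_equal(concept.point, [1.0, 1.0])
        assert concept.dd_value == 1.0

    def test_candidate_mode_equals_bruteforce(self, rng):
        for _ in range(20):
            bags = []
            for _ in range(rng.integers(2, 6)):
                bags.append(Bag(instances=rng.normal(size=(rng.integers(1, 4), 3)),
                                polarity="positive"))
            for _ in range(rng.integers(0, 4)):
                bags.append(Bag(instances=rng.normal(size=(rng.integers(1, 4), 3)),
                                polarity="negative"))
            concept = maximize_dd(bags)
            candidates = np.concatenate(
                [b.instances for b in bags if b.polarity == "positive"])
            values = [brute_force_dd(bags, c) for c in candidates]
            np.testing.assert_array_equal(
                concept.point, candidates[int(np.argmax(values))])

    def test_refined_matches_grid_search(self):
        bags = [
            Bag(instances=np.array([[0.0], [5.0]]), polarity="positive"),
            Bag(instances=np.array([[0.1]]), polarity="positive"),
            Bag(instances=np.array([[3.0]]), polarity="negative"),
        ]
        grid = np.arange(-1.0, 6.0, 1e-3)
        values = [log_dd(bags, np.array([g])) for g in grid]
        best_grid = grid[int(np.argmax(values))]
        concept = maximize_dd(bags, refine=True)
        assert abs(concept.point[0] - best_grid) <= 1e-3

    def test_known_concept_recovery(self):
        """Refinement moves the concept well inside the positive cloud:
        closer to the true center than any single instance, and scoring
        at least as high as the true center itself."""
        rng = np.random.default_rng(99)
        t_star = rng.normal(size=10)
        bags = [Bag(instances=t_star + 0.1 * rng.normal(size=(5, 10)),
                    polarity="positive") for _ in range(20)]
        bags += [Bag(instances=t_star + 8.0 + rng.normal(size=(5, 10)),
                     polarity="negative") for _ in range(20)]
        candidate = maximize_dd(bags, refine=False)
        refined = maximize_dd(bags, refine=True)
        d_refined = np.linalg.norm(refined.point - t_star)
        assert d_refined < np.linalg.norm(candidate.point - t_star)
        assert d_refined < 0.1
        assert refined.log_dd >= log_dd(bags, t_star)

    def test_refinement_never_worse_than_best_candidate(self):
        rng = np.random.default_rng(100)
        t_star = rng.normal(size=6)
        bags = [Bag(instances=t_star + 0.1 * rng.normal(size=(4, 6)),
                    polarity="positive") for _ in range(8)]
        plain = maximize_dd(bags, refine=False)
        refined = maximize_dd(bags, refine=True)
        assert refined.log_dd >= plain.log_dd


class TestLearnDictionary:
    def test_single_sample_per_class_atoms_are_samples(self):
        rng = np.random.default_rng(3)
        training = {1: rng.normal(size=(1, 6)), 2: rng.normal(size=(1, 6)) + 4}
        d = learn_dictionary(training)
        for i, code in enumerate([1, 2]):
            expected = training[code][0] / np.linalg.norm(training[code][0])
            np.testing.assert_allclose(d.atoms[i], expected, atol=1e-12)

    def test_synthetic_recovery_at_snr30(self):
        spec = synthetic.SceneSpec(rows=10, cols=10, bands=30, n_classes=2,
                                   snr_db=30.0, brightness_cv=0.0, seed=21)
        truth = synthetic.render_scene(spec)
        training = synthetic.sample_training(
            truth, per_class_counts={1: 10, 2: 10}, seed=5)
        d = learn_dictionary(training)
        unit = truth.endmembers / np.linalg.norm(truth.endmembers, axis=1,
                                                 keepdims=True)
        for i in range(2):
            assert d.atoms[i] @ unit[i] >= 0.99

    def test_atom_class_assignment_matches_truth(self):
        """With separable classes no atom is closer to another class's
        endmember than to its own."""
        spec = synthetic.phi_like_spec(snr_db=30.0, seed=17)
        truth = synthetic.render_scene(spec)
        training = synthetic.sample_training(truth, 0.5, seed=6)
        d = learn_dictionary(training)
        unit = truth.endmembers / np.linalg.norm(truth.endmembers, axis=1,
                                                 keepdims=True)
        sims = d.atoms @ unit.T
        np.testing.assert_array_equal(sims.argmax(axis=1) + 1, d.class_codes)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            learn_dictionary({1: np.ones((2, 3))})

    def test_bag_partition(self):
        training = {1: np.arange(10).reshape(5, 2).astype(float),
                    2: np.arange(6).reshape(3, 2) + 50.0}
        bags = make_bags(training, target_class=1, bag_size=2)
        positives = [b for b in bags if b.polarity == "positive"]
        negatives = [b for b in bags if b.polarity == "negative"]
        assert [b.instances.shape[0] for b in positives] == [2, 2, 1]
        assert [b.instances.shape[0] for b in negatives] == [2, 1]

    def test_multiple_atoms_per_class(self):
        rng = np.random.default_rng(8)
        training = {1: rng.normal(size=(5, 4)), 2: rng.normal(size=(5, 4)) + 6}
        d = learn_dictionary(training, atoms_per_class=2)
        assert d.n_atoms == 4
        np.testing.assert_array_equal(d.class_codes, [1, 1, 2, 2])
        # repeated maximization excludes the first pick, so atoms differ
        assert not np.allclose(d.atoms[0], d.atoms[1])
        assert not np.allclose(d.atoms[2], d.atoms[3])

    def test_metadata_recorded(self):
        rng = np.random.default_rng(1)
        training = {1: rng.normal(size=(2, 4)), 2: rng.normal(size=(2, 4)) + 3}
        d = learn_dictionary(training, bag_spec=BagSpec(bag_size=2), seed=77)
        assert d.meta["bag_size"] == 2
        assert d.meta["seed"] == 77
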