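"""Early vision: availability function, crowding scrambling, store persistence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr

from eyesearch.display import FIVE, SHAPE, TWO, generate_display, make_task_spec
from eyesearch.vision import (
    BLANK,
    AvailabilityParams,
    CrowdingParams,
    Snapshot,
    critical_spacing,
    detection_probability,
    form_crowding_groups,
    new_store,
    perceive,
    sample_snapshot,
    scramble_snapshot,
    update_store,
)


class TestDetectionProbability:
    def test_fifty_percent_at_threshold(self):
        # size equal to theta*ecc is, by construction, the 50% threshold
        assert detection_probability(2.0, 5.0, 0.4) == pytest.approx(0.5)

    def test_foveal_limit(self):
        assert detection_probability(2.1, 0.0, 0.4) == pytest.approx(1.0, abs=1e-4)

    def test_far_periphery_value(self):
        # independent evaluation: Phi((2.1 - 4.0)/0.5) = Phi(-3.8)
        expected = float(ndtr(-3.8))
        assert detection_probability(2.1, 10.0, 0.4) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(7.2e-5, abs=5e-6)

    def test_monotone_grid(self):
        eccs = np.linspace(0, 25, 40)
        p_ecc = detection_probability(2.1, eccs, 0.4)
        assert np.all(np.diff(p_ecc) < 0)
        sizes = np.linspace(0.5, 4.0, 30)
        p_size = np.array([detection_probability(s, 8.0, 0.4) for s in sizes])
        assert np.all(np.diff(p_size) > 0)

    @pytest.mark.parametrize("kwargs", [
        {"size": 0.0, "ecc": 1.0, "theta": 0.4},
        {"size": 2.0, "ecc": 1.0, "theta": 0.4, "sigma": 0.0},
        {"size": 2.0, "ecc": -1.0, "theta": 0.4},
    ])
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            detection_probability(**kwargs)


class TestSampleSnapshot:
    def test_theta_zero_is_veridical(self, rng):
        d = generate_display(make_task_spec("shape"), 12, "positive", rng)
        snap = sample_snapshot(d, (0.0, 0.0), AvailabilityParams(theta={SHAPE: 0.0}), rng)
        assert snap.values[SHAPE] == [o.properties[SHAPE] for o in d.objects]
        assert not snap.scrambled[SHAPE].any()

    def test_huge_theta_blanks_periphery(self, rng):
        d = generate_display(make_task_spec("shape"), 12, "negative", rng)
        snap = sample_snapshot(d, (0.0, 0.0), AvailabilityParams(theta={SHAPE: 1e6}), rng)
        assert all(v is BLANK for v in snap.values[SHAPE])

    def test_empirical_rate_matches_closed_form(self, rng):
        """Detection frequency at fixed geometry matches the normal CDF."""
        d = generate_display(make_task_spec("shape"), 1, "negative", rng)
        eye = (0.0, 0.0)
        ecc = float(np.linalg.norm(d.positions[0]))
        p = detection_probability(2.1, ecc, 0.3)
        avail = AvailabilityParams(theta={SHAPE: 0.3})
        n = 20_000
        hits = sum(
            sample_snapshot(d, eye, avail, rng).values[SHAPE][0] is not BLANK
            for _ in range(n)
        )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 5 * se


class TestCrowdingGroups:
    def test_critical_spacing_is_half_ecc(self):
        assert critical_spacing(10.0) == 5.0
        assert critical_spacing(0.0) == 0.0

    def _two_object_display(self, pos_a, pos_b):
        spec = make_task_spec("shape")
        d = generate_display(spec, 2, "negative", np.random.default_rng(0))
        d.objects[0].position = pos_a
        d.objects[1].position = pos_b
        d.__dict__.pop("positions", None)
        d.__dict__.pop("distance_matrix", None)
        return d

    def test_within_spacing_groups(self):
        # ecc 10 and dist 4 < 5 -> grouped
        d = self._two_object_display((10.0, 0.0), (10.0, 4.0))
        groups = form_crowding_groups(d, (0.0, 0.0))
        assert sorted(map(sorted, groups)) == [[0, 1]]

    def test_outside_spacing_singletons(self):
        # both ecc 2, dist 1.5 > 1 -> singletons
        d = self._two_object_display((2.0, 0.0), (2.0, 1.5))
        groups = form_crowding_groups(d, (0.0, 0.0))
        assert sorted(map(sorted, groups)) == [[0], [1]]

    def test_foveal_object_directional_rule(self):
        # object at the eye (ecc 0) and neighbor at dist 3 with ecc 3:
        # neither directional test passes -> singletons
        d = self._two_object_display((0.0, 0.0), (3.0, 0.0))
        groups = form_crowding_groups(d, (0.0, 0.0))
        assert sorted(map(sorted, groups)) == [[0], [1]]

    def test_partition_covers_all_objects(self, rng):
        d = generate_display(make_task_spec("shape"), 18, "negative", rng)
        groups = form_crowding_groups(d, (3.0, -2.0))
        flat = sorted(i for g in groups for i in g)
        assert flat == list(range(18))


def _snapshot(values, eye=(0.0, 0.0)):
    return Snapshot(
        eye=eye,
        values={SHAPE: list(values)},
        scrambled={SHAPE: np.zeros(len(values), dtype=bool)},
    )


class TestScrambleSnapshot:
    def test_phi_zero_identity(self, rng):
        snap = _snapshot([TWO, FIVE, BLANK])
        out = scramble_snapshot(snap, [[0, 1, 2]], CrowdingParams(phi={SHAPE: 0.0}), rng)
        assert out.values[SHAPE] == snap.values[SHAPE]
        assert not out.scrambled[SHAPE].any()

    def test_singletons_unchanged(self, rng):
        snap = _snapshot([TWO, FIVE])
        out = scramble_snapshot(snap, [[0], [1]], CrowdingParams(phi={SHAPE: 1.0}), rng)
        assert out.values[SHAPE] == [TWO, FIVE]

    def test_two_object_exchange_probability(self, rng):
        """Two sequential Bernoulli(phi) swap decisions; an odd number of
        swaps exchanges the pair, so P(exchange) = 2*phi*(1-phi) = 0.18
        at phi = 0.1 (exhaustive enumeration of the four outcomes)."""
        crowd = CrowdingParams(phi={SHAPE: 0.1})
        n = 40_000
        exchanged = 0
        for _ in range(n):
            out = scramble_snapshot(_snapshot([TWO, FIVE]), [[0, 1]], crowd, rng)
            exchanged += out.values[SHAPE] == [FIVE, TWO]
        p = 0.18
        se = np.sqrt(p * (1 - p) / n)
        assert abs(exchanged / n - p) < 5 * se

    @given(
        values=st.lists(st.sampled_from([TWO, FIVE, BLANK]), min_size=2, max_size=8),
        phi=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_multiset_conserved(self, values, phi, seed):
        rng = np.random.default_rng(seed)
        snap = _snapshot(values)
        out = scramble_snapshot(snap, [list(range(len(values)))], CrowdingParams(phi={SHAPE: phi}), rng)
        assert sorted(out.values[SHAPE], key=str) == sorted(values, key=str)


class TestUpdateStore:
    def _store_with(self, value, display):
        store = new_store(display)
        store.values[SHAPE][0] = value
        return store

    def test_unavailable_blank_retains(self, rng):
        d = generate_display(make_task_spec("shape"), 1, "positive", rng)
        store = self._store_with(TWO, d)
        update_store(store, _snapshot([BLANK]))
        assert store.values[SHAPE][0] == TWO

    def test_acquisition_overwrites(self, rng):
        d = generate_display(make_task_spec("shape"), 1, "negative", rng)
        store = self._store_with(BLANK, d)
        update_store(store, _snapshot([FIVE]))
        assert store.values[SHAPE][0] == FIVE

    def test_scrambled_blank_erases(self, rng):
        d = generate_display(make_task_spec("shape"), 1, "positive", rng)
        store = self._store_with(TWO, d)
        snap = _snapshot([BLANK])
        snap.scrambled[SHAPE][0] = True
        update_store(store, snap)
        assert store.values[SHAPE][0] is BLANK


class TestPerceive:
    def test_perfect_vision_matches_ground_truth(self, rng):
        d = generate_display(make_task_spec("conjunction"), 12, "positive", rng)
        avail = AvailabilityParams(theta={"color": 0.0, "orientation": 0.0})
        store = new_store(d)
        perceive(d, (0.0, 0.0), avail, CrowdingParams(), store, rng)
        for prop in d.task.properties:
            assert store.values[prop] == [o.properties[prop] for o in d.objects]

    def test_phi_zero_equals_availability_only(self):
        """With no crowding the pipeline consumes the same random stream as
        bare availability sampling, so shared seeds agree exactly."""
        d = generate_display(make_task_spec("shape"), 18, "positive", np.random.default_rng(3))
        avail = AvailabilityParams(theta={SHAPE: 0.4})
        store_a = new_store(d)
        perceive(d, (1.0, 2.0), avail, CrowdingParams(phi={SHAPE: 0.0}), store_a, np.random.default_rng(99))
        snap = sample_snapshot(d, (1.0, 2.0), avail, np.random.default_rng(99))
        store_b = update_store(new_store(d), snap)
        assert store_a.values == store_b.values

    def test_shape_negative_never_contains_target_value(self, rng):
        """No target shape exists on a negative display, so scrambling can
        never manufacture one (the false-alarm asymmetry)."""
        avail = AvailabilityParams(theta={SHAPE: 0.4})
        crowd = CrowdingParams(phi={SHAPE: 0.3})
        for _ in range(200):
            d = generate_display(make_task_spec("shape"), 18, "negative", rng)
            store = new_store(d)
            for eye in [(0.0, 0.0), (5.0, 5.0), (-6.0, 2.0)]:
                perceive(d, eye, avail, crowd, store, rng)
            assert TWO not in store.values[SHAPE]

    def test_conjunction_negative_can_form_illusory_target(self, rng):
        """Scrambling abundant color/orientation values can assemble a
        red-vertical percept on a target-absent conjunction display."""
        avail = AvailabilityParams(theta={"color": 0.11, "orientation": 0.20})
        crowd = CrowdingParams(phi={"color": 0.025, "orientation": 0.025})
        found = 0
        for _ in range(2000):
            d = generate_display(make_task_spec("conjunction"), 18, "negative", rng)
            store = new_store(d)
            perceive(d, (0.0, 0.0), avail, crowd, store, rng)
            pairs = zip(store.values["color"], store.values["orientation"])
            found += any(c == "red" and o == "vertical" for c, o in pairs)
        assert found > 0

    def test_positive_display_can_form_illusory_distractor(self, rng):
        """With crowding, the target can end up holding a distractor value."""
        avail = AvailabilityParams(theta={SHAPE: 0.4})
        crowd = CrowdingParams(phi={SHAPE: 0.3})
        seen = False
        for _ in range(500):
            d = generate_display(make_task_spec("shape"), 18, "positive", rng)
            store = new_store(d)
            for eye in [(0.0, 0.0), (2.0, 1.0)]:
                perceive(d, eye, avail, crowd, store, rng)
            if store.values[SHAPE][d.target_index] == FIVE:
                seen = True
                break
        assert seen
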