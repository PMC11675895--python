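"""Aggregation rules, sharing masks, DP noise, dropout schedule, orchestration."""

import numpy as np
import pytest

from fedseg3d.augment import AugmentConfig
from fedseg3d.federation import (
    ClientState,
    FedConfig,
    add_dp_noise,
    apply_mask,
    dropout_participants,
    fedavg_aggregate,
    masked_aggregate,
    run_federation,
    sample_share_mask,
)
from fedseg3d.model import ModelConfig, WeightSet, build_model, train_local
from fedseg3d.phantoms import PhantomSpec, generate_case
from fedseg3d.preprocess import normalize_volume


def random_weightset(rng, layers=((3,), (2, 4), (5,))):
    return WeightSet(
        (f"layer{i}", rng.normal(size=shape)) for i, shape in enumerate(layers)
    )


def make_phantom_pairs(n, seed=0, shape=(16, 16, 16)):
    pairs = []
    for i in range(n):
        spec = PhantomSpec(
            volume_shape=shape, tumor_center=(8, 8, 8),
            region_radii=(1.5, 3.0, 5.0), noise_sd=0.02, seed=seed + i,
        )
        case = generate_case(spec, case_id=f"p{i}")
        pairs.append((normalize_volume(case.volume), case.labels))
    return pairs


class TestFedAvg:
    def test_identical_clients_fixed_point(self, rng):
        w = random_weightset(rng)
        out = fedavg_aggregate([w, w.copy(), w.copy()], [3, 1, 2])
        for k in w:
            np.testing.assert_allclose(out[k], w[k])

    def test_weighted_mean_example(self):
        a = WeightSet([("w", np.array([0.0]))])
        b = WeightSet([("w", np.array([4.0]))])
        out = fedavg_aggregate([a, b], [1, 3])
        assert out["w"][0] == pytest.approx(3.0)

    def test_single_client_identity(self, rng):
        w = random_weightset(rng)
        out = fedavg_aggregate([w], [5])
        for k in w:
            np.testing.assert_allclose(out[k], w[k])

    def test_matches_weighted_mean_oracle(self, rng):
        for _ in range(50):
            n_clients = int(rng.integers(2, 6))
            ws = [random_weightset(rng) for _ in range(n_clients)]
            nk = rng.integers(1, 100, size=n_clients).tolist()
            out = fedavg_aggregate(ws, nk)
            for k in ws[0]:
                oracle = sum(w[k] * n for w, n in zip(ws, nk)) / sum(nk)
                np.testing.assert_allclose(out[k], oracle, rtol=1e-12)

    def test_equal_counts_reduce_to_plain_mean(self, rng):
        ws = [random_weightset(rng) for _ in range(4)]
        out = fedavg_aggregate(ws, [7, 7, 7, 7])
        for k in ws[0]:
            np.testing.assert_allclose(out[k], np.mean([w[k] for w in ws], axis=0))

    def test_shape_mismatch_error(self, rng):
        a = WeightSet([("w", np.zeros(3))])
        b = WeightSet([("w", np.zeros(4))])
        with pytest.raises(ValueError):
            fedavg_aggregate([a, b], [1, 1])


class TestShareMask:
    def test_full_sharing_mask_all_ones(self, rng):
        m = sample_share_mask({"a": (10,), "b": (3, 3)}, (1.0, 1.0), rng)
        assert all(np.all(v == 1) for v in m.masks.values())
        assert m.q_effective == 1.0

    def test_exact_count_at_fixed_q(self, rng):
        m = sample_share_mask({"a": (100,)}, (0.45, 0.45), rng)
        assert m.masks["a"].sum() == 45

    def test_minimum_one_per_layer(self, rng):
        m = sample_share_mask({"tiny": (2,)}, (0.1, 0.1), rng)
        assert m.masks["tiny"].sum() == 1

    def test_deterministic_under_fixed_rng(self):
        a = sample_share_mask({"a": (50,)}, (0.4, 0.5), np.random.default_rng(3))
        b = sample_share_mask({"a": (50,)}, (0.4, 0.5), np.random.default_rng(3))
        assert a.q == b.q
        np.testing.assert_array_equal(a.masks["a"], b.masks["a"])

    def test_q_drawn_within_range(self, rng):
        for _ in range(20):
            m = sample_share_mask({"a": (200,)}, (0.4, 0.5), rng)
            assert 0.4 <= m.q <= 0.5
            assert abs(m.q_effective - m.q) <= 0.5 / 200 + 1e-9


class TestApplyMask:
    def test_all_ones_identity(self, rng):
        w = random_weightset(rng)
        m = sample_share_mask({k: v.shape for k, v in w.items()}, (1.0, 1.0), rng)
        out = apply_mask(w, m)
        for k in w:
            np.testing.assert_array_equal(out[k], w[k])

    def test_masked_positions_zeroed_input_untouched(self, rng):
        w = random_weightset(rng, layers=((20,),))
        snapshot = w.copy()
        m = sample_share_mask({"layer0": (20,)}, (0.5, 0.5), rng)
        out = apply_mask(w, m)
        assert (out["layer0"] != 0).sum() == m.masks["layer0"].sum()
        np.testing.assert_array_equal(w["layer0"], snapshot["layer0"])


def brute_force_masked_aggregate(prev, shared):
    """Per-position loop oracle for the zero-weight rules."""
    out = WeightSet()
    for k, pv in prev.items():
        res = np.empty_like(pv)
        flat_prev = pv.reshape(-1)
        flats = [w[k].reshape(-1) for w in shared]
        flat_out = res.reshape(-1)
        for i in range(flat_prev.size):
            vals = [f[i] for f in flats if f[i] != 0]
            if not vals:
                new = flat_prev[i]
            elif len(vals) == 1:
                new = vals[0]
            else:
                new = sum(vals) / len(vals)
            flat_out[i] = 0.5 * (flat_prev[i] + new)
        out[k] = res
    return out


class TestMaskedAggregate:
    @pytest.mark.parametrize(
        "prev, clients, expected",
        [(2.0, (0.0, 0.0), 2.0), (2.0, (0.0, 5.0), 3.5), (2.0, (2.0, 4.0), 2.5)],
    )
    def test_rule_table(self, prev, clients, expected):
        prev_w = WeightSet([("w", np.array([prev]))])
        shared = [WeightSet([("w", np.array([c]))]) for c in clients]
        out = masked_aggregate(prev_w, shared)
        assert out["w"][0] == pytest.approx(expected)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            n_clients = int(rng.integers(2, 6))
            prev = random_weightset(rng, layers=((7,), (3, 4)))
            shared = []
            for _ in range(n_clients):
                w = random_weightset(rng, layers=((7,), (3, 4)))
                for k in w:  # random zero patterns incl. all-zero positions
                    w[k][rng.random(w[k].shape) < rng.uniform(0.2, 0.9)] = 0.0
                shared.append(w)
            out = masked_aggregate(prev, shared)
            oracle = brute_force_masked_aggregate(prev, shared)
            for k in prev:
                np.testing.assert_array_equal(out[k], oracle[k])

    def test_convexity_of_output(self, rng):
        prev = random_weightset(rng, layers=((50,),))
        shared = []
        for _ in range(3):
            w = random_weightset(rng, layers=((50,),))
            w["layer0"][rng.random(50) < 0.5] = 0.0
            shared.append(w)
        out = masked_aggregate(prev, shared)["layer0"]
        stack = np.stack([w["layer0"] for w in shared])
        for i in range(50):
            vals = [prev["layer0"][i]] + [v for v in stack[:, i] if v != 0]
            assert min(vals) - 1e-12 <= out[i] <= max(vals) + 1e-12

    def test_inputs_unmodified(self, rng):
        prev = random_weightset(rng)
        shared = [random_weightset(rng) for _ in range(2)]
        snap_prev, snap_shared = prev.copy(), [w.copy() for w in shared]
        masked_aggregate(prev, shared)
        for k in prev:
            np.testing.assert_array_equal(prev[k], snap_prev[k])
            for w, s in zip(shared, snap_shared):
                np.testing.assert_array_equal(w[k], s[k])


class TestDPNoise:
    def test_zero_sd_exact_identity(self, rng):
        w = random_weightset(rng)
        out = add_dp_noise(w, 0.0, rng)
        for k in w:
            np.testing.assert_array_equal(out[k], w[k])
        vol = rng.normal(size=(4, 4, 4, 4))
        np.testing.assert_array_equal(add_dp_noise(vol, 0.0, rng), vol)

    def test_mean_shift_within_clt_bound(self, rng):
        w = WeightSet([("w", np.zeros(10_000))])
        sd = 0.01
        out = add_dp_noise(w, sd, rng)
        assert abs(out["w"].mean()) <= 4 * sd / np.sqrt(10_000)
        assert out["w"].std() == pytest.approx(sd, rel=0.1)

    def test_independent_streams_differ(self, rng):
        w = random_weightset(rng)
        a = add_dp_noise(w, 0.01, np.random.default_rng(1))
        b = add_dp_noise(w, 0.01, np.random.default_rng(2))
        assert any(not np.array_equal(a[k], b[k]) for k in w)


class TestDropoutSchedule:
    def test_outside_window_all_participate(self, rng):
        assert dropout_participants(30, 4, (50, 150, 10), rng) == [0, 1, 2, 3]

    def test_window_start_is_inclusive(self, rng):
        parts = dropout_participants(50, 4, (50, 150, 10), rng)
        assert len(parts) == 3

    def test_off_period_epochs_keep_everyone(self, rng):
        assert len(dropout_participants(55, 4, (50, 150, 10), rng)) == 4
        assert len(dropout_participants(60, 4, (50, 150, 10), rng)) == 3

    def test_dropped_client_uniform_over_runs(self):
        dropped = set()
        for s in range(40):
            parts = dropout_participants(50, 4, (50, 150, 10),
                                         np.random.default_rng(s))
            dropped |= {0, 1, 2, 3} - set(parts)
        assert dropped == {0, 1, 2, 3}


TINY_MODEL = ModelConfig(depth=2, base_filters=4, seed=1)


def make_clients(n_clients, cases_per_client, seed=0):
    pairs = make_phantom_pairs(n_clients * cases_per_client, seed=seed)
    return [
        ClientState(id=i, cases=pairs[i * cases_per_client : (i + 1) * cases_per_client])
        for i in range(n_clients)
    ]


class TestRunFederation:
    def test_full_mode_single_round_is_algorithm_one(self):
        # no noise, no dropout, no augmentation, one case per client: the
        # client update is train_local from the broadcast weights, and the
        # global update must equal the n_k-weighted mean of those updates
        clients = make_clients(2, 1, seed=3)
        fed = FedConfig(K=2, E=2, eta=1e-3, total_epochs=2, mode="full",
                        noise_sd_data=0.0, noise_sd_model=0.0,
                        dropout_window=(10**6, 10**6 + 1, 1), seed=42)
        history, global_w = run_federation(fed, TINY_MODEL, clients)
        assert len(history) == 1 and history[0].participants == [0, 1]
        model, w0 = build_model(TINY_MODEL)
        updates = []
        for c in clients:
            # single case + no augmentation: rng only shuffles one element,
            # so any rng reproduces the update
            w, _ = train_local(model, w0, c.cases, epochs=2, lr=1e-3,
                               rng=np.random.default_rng(0))
            updates.append(w)
        expected = fedavg_aggregate(updates, [1, 1])
        for k in global_w:
            np.testing.assert_allclose(global_w[k], expected[k], atol=1e-7)

    def test_partial_full_sharing_reduces_to_prev_new_average(self):
        clients = make_clients(2, 1, seed=9)
        fed = FedConfig(K=2, E=1, eta=1e-3, total_epochs=1, mode="partial",
                        q_range=(1.0, 1.0), noise_sd_data=0.0, noise_sd_model=0.0,
                        dropout_window=(10**6, 10**6 + 1, 1), seed=5)
        _, global_w = run_federation(fed, TINY_MODEL, clients)
        model, w0 = build_model(TINY_MODEL)
        updates = [
            train_local(model, w0, c.cases, epochs=1, lr=1e-3,
                        rng=np.random.default_rng(0))[0]
            for c in clients
        ]
        # with an all-ones mask the engine must reduce to the zero-weight
        # rules applied to the raw updates, then the (prev + new)/2 average
        expected = masked_aggregate(w0, updates)
        for k in global_w:
            np.testing.assert_allclose(global_w[k], expected[k], atol=1e-7)

    def test_end_to_end_replay_identical(self):
        clients = make_clients(2, 2, seed=20)
        fed = FedConfig(K=2, E=1, total_epochs=3, mode="partial", eta=1e-3,
                        dropout_window=(2, 3, 1), seed=77)
        aug = AugmentConfig()
        h1, w1 = run_federation(fed, TINY_MODEL, clients, augment_cfg=aug)
        h2, w2 = run_federation(fed, TINY_MODEL, clients, augment_cfg=aug)
        assert [r.participants for r in h1] == [r.participants for r in h2]
        assert [r.q_by_client for r in h1] == [r.q_by_client for r in h2]
        for k in w1:
            np.testing.assert_array_equal(w1[k], w2[k])

    def test_dropout_excludes_exactly_one_client(self):
        clients = make_clients(3, 1, seed=30)
        # every round's starting epoch hits the window period
        fed = FedConfig(K=3, E=1, total_epochs=2, mode="full", eta=1e-3,
                        noise_sd_data=0.0, noise_sd_model=0.0,
                        dropout_window=(1, 10, 1), seed=8)
        history, _ = run_federation(fed, TINY_MODEL, clients)
        for r in history:
            assert len(r.participants) == 2

    def test_dropped_client_cannot_influence_update(self):
        # perturbation test: corrupt the excluded client's data; the global
        # weights after the dropout round must not change
        fed = FedConfig(K=2, E=1, total_epochs=1, mode="full", eta=1e-3,
                        noise_sd_data=0.0, noise_sd_model=0.0,
                        dropout_window=(1, 2, 1), seed=13)
        clients = make_clients(2, 1, seed=40)
        h1, w1 = run_federation(fed, TINY_MODEL, clients)
        (excluded,) = {0, 1} - set(h1[0].participants)
        perturbed = make_clients(2, 1, seed=40)
        vol, lab = perturbed[excluded].cases[0]
        perturbed[excluded].cases[0] = (vol + 100.0, lab)
        h2, w2 = run_federation(fed, TINY_MODEL, perturbed)
        assert h2[0].participants == h1[0].participants
        for k in w1:
            np.testing.assert_array_equal(w1[k], w2[k])


class TestFedConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(C=0.0), dict(E=0), dict(q_range=(0.0, 0.5)), dict(q_range=(0.6, 0.5)),
         dict(mode="half"), dict(total_epochs=10, E=3)],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            FedConfig(**kw)
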