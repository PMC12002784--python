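"""Network contracts, early stopping, and cross-validation structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trusseg._nn import unet_parameter_count
from trusseg.radial_geometry import RadialGeometry, extract_stack
from trusseg.seg_model import (
    CasePlanes,
    ModelConfig,
    TrainConfig,
    build_network,
    crossval,
    predict_stack,
    load_model,
    save_model,
    stopping_epoch,
    train_fold,
)
from trusseg.volume_io import Volume3D


def tiny_cases(n_cases=6, n_planes=2, size=8, seed=0):
    rng = np.random.default_rng(seed)
    return [
        CasePlanes(
            case_id=f"c{i}",
            x=rng.random((n_planes, 3, size, size)).astype(np.float32),
            y=(rng.random((n_planes, 2, size, size)) > 0.5).astype(np.float32),
        )
        for i in range(n_cases)
    ]


TINY_MODEL = ModelConfig(depth=2, base_width=4)
FAST_TRAIN = TrainConfig(max_iterations=1, patience=10, batch_size=4, seed=3)


def test_output_shape_and_probability_range(rng):
    model = build_network(TINY_MODEL, seed=1)
    x = rng.normal(size=(3, 3, 12, 20)).astype(np.float32)  # non-square, non-multiple
    probs = model.predict(x)
    assert probs.shape == (3, 2, 12, 20)
    assert probs.min() >= 0.0 and probs.max() <= 1.0


def test_all_zero_input_produces_valid_probabilities():
    model = build_network(TINY_MODEL, seed=1)
    probs = model.predict(np.zeros((1, 3, 8, 8), dtype=np.float32))
    assert np.isfinite(probs).all()
    assert probs.min() >= 0.0 and probs.max() <= 1.0


def test_parameter_count_matches_hand_derived_formula():
    # depth 2, base 4: channels 4, 8; bottleneck 16; per-conv count
    # k^2*cin*cout + cout, two convs per block
    def conv(ci, co, k=3):
        return k * k * ci * co + co

    expected = (
        conv(3, 4) + conv(4, 4)  # encoder level 0
        + conv(4, 8) + conv(8, 8)  # encoder level 1
        + conv(8, 16) + conv(16, 16)  # bottleneck
        + conv(16 + 8, 8) + conv(8, 8)  # decoder level 1 (upsampled+skip)
        + conv(8 + 4, 4) + conv(4, 4)  # decoder level 0
        + conv(4, 2, k=1)  # output head
    )
    assert expected == 7542
    model = build_network(ModelConfig(depth=2, base_width=4), seed=0)
    assert model.n_parameters == expected
    assert unet_parameter_count(3, 2, 2, 4) == expected


def test_input_smaller_than_receptive_step_rejected():
    model = build_network(ModelConfig(depth=5, base_width=4), seed=0)
    with pytest.raises(ValueError, match="smaller than 2\\^depth"):
        model.predict(np.zeros((1, 3, 16, 16), dtype=np.float32))


def test_invalid_channel_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(in_channels=1)
    with pytest.raises(ValueError):
        ModelConfig(out_channels=3)
    with pytest.raises(ValueError):
        ModelConfig(depth=1)


def brute_force_stop(metrics, patience, cap):
    """Independent evaluation of the stopping rule: scan prefixes and halt
    at the first epoch lying `patience` epochs past the running argmax."""
    for e in range(1, min(len(metrics), cap) + 1):
        prefix = metrics[:e]
        best_epoch = int(np.argmax(prefix)) + 1
        if e - best_epoch >= patience:
            return e
    return min(len(metrics), cap)


@given(
    seq=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=70),
    patience=st.integers(1, 15),
    cap=st.integers(1, 65),
)
@settings(deadline=None, derandomize=True)
def test_stopping_rule_matches_bruteforce_property(seq, patience, cap):
    assert stopping_epoch(seq, patience, cap) == brute_force_stop(seq, patience, cap)


def test_stopping_rule_matches_bruteforce_on_random_sequences(rng):
    for _ in range(100):
        seq = rng.random(70).tolist()
        patience = int(rng.integers(1, 15))
        cap = int(rng.integers(5, 65))
        assert stopping_epoch(seq, patience, cap) == brute_force_stop(seq, patience, cap)


def test_training_stops_at_patience_after_last_improvement():
    # validation metric never improves after epoch 3 -> stop at epoch 13
    cases = tiny_cases(2)
    model = build_network(TINY_MODEL, seed=0)
    metric_by_epoch = lambda model, epoch: {1: 0.1, 2: 0.2, 3: 0.3}.get(epoch, 0.25)
    cfg = TrainConfig(max_iterations=60, patience=10, batch_size=4, seed=1)
    _, history = train_fold(model, cases[:1], cases[1:], cfg,
                            val_metric_fn=metric_by_epoch)
    assert len(history) == 13


def test_training_runs_full_length_when_always_improving():
    cases = tiny_cases(2)
    model = build_network(TINY_MODEL, seed=0)
    cfg = TrainConfig(max_iterations=60, patience=10, batch_size=4, seed=1)
    _, history = train_fold(model, cases[:1], cases[1:], cfg,
                            val_metric_fn=lambda m, e: e / 100.0)
    assert len(history) == 60


def test_training_history_is_deterministic_under_seed():
    cases = tiny_cases(3)
    cfg = TrainConfig(max_iterations=3, patience=10, batch_size=4, seed=5)
    _, h1 = train_fold(build_network(TINY_MODEL, seed=2), cases[:2], cases[2:], cfg)
    _, h2 = train_fold(build_network(TINY_MODEL, seed=2), cases[:2], cases[2:], cfg)
    assert h1 == h2


def test_empty_training_set_rejected():
    cases = tiny_cases(1)
    model = build_network(TINY_MODEL, seed=0)
    with pytest.raises(ValueError, match="empty"):
        train_fold(model, [], cases, FAST_TRAIN)


def test_best_epoch_weights_are_retained():
    cases = tiny_cases(2)
    model = build_network(TINY_MODEL, seed=0)
    snapshots = {}

    def metric(m, epoch):
        snapshots[epoch] = m.net.state()
        return {1: 0.5, 2: 0.9}.get(epoch, 0.1)  # best at epoch 2

    cfg = TrainConfig(max_iterations=6, patience=3, batch_size=4, seed=1)
    model, history = train_fold(model, cases[:1], cases[1:], cfg,
                                val_metric_fn=metric)
    assert len(history) == 5  # 2 + patience 3
    for got, best in zip(model.net.state(), snapshots[2]):
        np.testing.assert_array_equal(got, best)


def _fake_train(model, train_cases, val_cases, cfg, val_metric_fn=None):
    return model, [{"epoch": 1, "train_loss": 0.0, "val_dsc": 1.0}]


def test_crossval_partition_properties():
    cases = tiny_cases(10)
    result = crossval(cases, TINY_MODEL, TrainConfig(seed=4), train_fn=_fake_train)
    folds = {}
    for cid, fi in result.fold_assignment.items():
        folds.setdefault(fi, []).append(cid)
    assert len(result.fold_assignment) == 10  # every case validates once
    assert sorted(len(v) for v in folds.values()) == [2, 2, 2, 2, 2]
    assert set(result.oof_predictions) == {c.case_id for c in cases}


def test_crossval_fold_sizes_differ_by_at_most_one():
    cases = tiny_cases(13)
    result = crossval(cases, TINY_MODEL, TrainConfig(seed=4), train_fn=_fake_train)
    sizes = np.bincount(list(result.fold_assignment.values()), minlength=5)
    assert sizes.max() - sizes.min() <= 1
    assert sizes.sum() == 13


def test_crossval_assignment_is_seeded():
    cases = tiny_cases(10)
    r1 = crossval(cases, TINY_MODEL, TrainConfig(seed=8), train_fn=_fake_train)
    r2 = crossval(cases, TINY_MODEL, TrainConfig(seed=8), train_fn=_fake_train)
    assert r1.fold_assignment == r2.fold_assignment


def test_crossval_rejects_fewer_cases_than_folds():
    with pytest.raises(ValueError):
        crossval(tiny_cases(4), TINY_MODEL, TrainConfig(n_folds=5), train_fn=_fake_train)


def test_predict_stack_is_deterministic(rng):
    vol = Volume3D(rng.random((16, 16, 8)))
    geom = RadialGeometry.from_volume(vol, angular_interval=45.0,
                                      in_plane_spacing=1.0)
    stack = extract_stack(vol, geom)
    model = build_network(TINY_MODEL, seed=6)
    p1 = predict_stack(model, stack)
    p2 = predict_stack(model, stack)
    assert len(p1) == geom.n_planes
    for a, b in zip(p1, p2):
        np.testing.assert_array_equal(a.prostate_prob, b.prostate_prob)
        np.testing.assert_array_equal(a.zone_prob, b.zone_prob)
        assert 0.0 <= a.prostate_prob.min() and a.prostate_prob.max() <= 1.0


def test_predict_stack_rejects_geometry_mismatch(rng):
    vol = Volume3D(rng.random((16, 16, 8)))
    geom_train = RadialGeometry.from_volume(vol, angular_interval=45.0,
                                            in_plane_spacing=1.0)
    geom_other = RadialGeometry.from_volume(vol, angular_interval=30.0,
                                            in_plane_spacing=1.0)
    model = build_network(TINY_MODEL, seed=6)
    model.geometry = geom_train
    with pytest.raises(ValueError, match="geometry"):
        predict_stack(model, extract_stack(vol, geom_other))


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_network(TINY_MODEL, seed=9)
    x = rng.random((1, 3, 8, 8)).astype(np.float32)
    before = model.predict(x)
    save_model(model, tmp_path / "ckpt.npz")
    back = load_model(tmp_path / "ckpt.npz")
    np.testing.assert_array_equal(back.predict(x), before)
    assert back.config == model.config
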