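"""Network structure, augmentation, checkpoint selection and inference decoding."""
import numpy as np
import pytest

from renovol.errors import ParameterError
from renovol.imaging import ClassScheme
from renovol.nn import (
    AugmentConfig,
    NetworkConfig,
    ProbabilityMap,
    Tensor,
    augment,
    build_network,
    no_grad,
    probabilities_to_labels,
    select_best_epoch,
    sliding_window_probabilities,
)


def test_paper_config_prints_published_dimensions():
    cfg = NetworkConfig.paper()
    assert cfg.patch_size == (96, 96, 96)
    assert cfg.hidden == 768
    assert cfg.ffn == 3072
    assert cfg.heads == 12
    assert cfg.blocks == 12
    assert cfg.decoding_stages == 3
    assert cfg.in_channels == 1 and cfg.out_channels == 3


def test_invalid_configs_rejected():
    with pytest.raises(ParameterError):
        NetworkConfig(patch_size=(90, 96, 96))  # not divisible by token edge
    with pytest.raises(ParameterError):
        NetworkConfig(hidden=100, heads=12)
    with pytest.raises(ParameterError):
        NetworkConfig(token_patch=8)  # inconsistent with 3 decoding stages


def test_tiny_forward_shape_and_determinism(rng):
    net = build_network(NetworkConfig.tiny(0)).eval()
    x = rng.random((1, 64, 64, 64), dtype=np.float32)
    with no_grad():
        a = net(Tensor(x)).data
        b = net(Tensor(x)).data
    assert a.shape == (3, 64, 64, 64)
    np.testing.assert_array_equal(a, b)


def test_skip_taps_evenly_spaced():
    assert NetworkConfig.paper().skip_taps == (9, 6, 3)
    assert NetworkConfig.tiny().skip_taps == (3, 2, 1)


def test_parameter_count_matches_layer_by_layer_tally():
    """Independent analytic tally of the tiny preset's parameters."""
    cfg = NetworkConfig.tiny(0)
    h, ffn, blocks = cfg.hidden, cfg.ffn, cfg.blocks
    n_tok = 4 * 4 * 4
    embed = (16**3 * 1) * h + h + n_tok * h  # projection W+b, positional table

    per_block = (
        2 * h                      # ln1
        + h * 3 * h + 3 * h        # qkv
        + h * h + h                # attention out projection
        + 2 * h                    # ln2
        + h * ffn + ffn            # mlp fc1
        + ffn * h + h              # mlp fc2
    )

    def conv3(ci, co):
        return co * ci * 27 + co

    def conv1(ci, co):
        return co * ci + co

    def bn(c):
        return 2 * c

    def deconv(ci, co):
        return co * 8 * ci + co

    c0, c1, c2, c3 = cfg.decoder_channels
    decoder = conv3(h, c0) + bn(c0)                      # token projection
    decoder += conv3(h, c0) + bn(c0)                     # skip level 0
    decoder += deconv(h, c1) + conv3(c1, c1) + bn(c1)    # skip level 1
    decoder += deconv(h, c2) + conv3(c2, c2) + bn(c2)    # skip level 2 (two ups)
    decoder += deconv(c2, c2) + conv3(c2, c2) + bn(c2)
    for ci, co in ((c0, c1), (c1, c2), (c2, c3)):        # stage bodies + upsamplers
        decoder += conv3(2 * ci, ci) + bn(ci) + conv3(ci, ci) + bn(ci) + deconv(ci, co)
    decoder += deconv(c3, c3)                            # head upsampling
    decoder += conv3(1, c3) + bn(c3)                     # input skip
    decoder += conv3(2 * c3, c3) + bn(c3)                # fusion
    decoder += conv1(c3, 3)                              # class scores

    expected = embed + blocks * per_block + decoder
    assert build_network(cfg).num_params() == expected


# --- augmentation ---------------------------------------------------------

def test_augment_identity_at_p_zero(rng):
    img = rng.random((8, 8, 8))
    lab = rng.integers(0, 3, size=(8, 8, 8)).astype(np.uint8)
    out_img, out_lab = augment(img, lab, AugmentConfig(p=0.0), rng=rng)
    np.testing.assert_array_equal(out_img, img)
    np.testing.assert_array_equal(out_lab, lab)


def test_flip_is_involution():
    img = np.random.default_rng(0).random((6, 6, 6))
    lab = (img > 0.5).astype(np.uint8)
    cfg = AugmentConfig(p=1.0, transforms=("flip",), flip_axis=1)
    once_img, once_lab = augment(img, lab, cfg, seed=0)
    twice_img, twice_lab = augment(once_img, once_lab, cfg, seed=0)
    np.testing.assert_array_equal(twice_img, img)
    np.testing.assert_array_equal(twice_lab, lab)


def test_augment_seeded_reproducibility(rng):
    img = rng.random((10, 12, 12))
    lab = rng.integers(0, 4, size=(10, 12, 12)).astype(np.uint8)
    cfg = AugmentConfig(p=1.0)
    a_img, a_lab = augment(img, lab, cfg, seed=77)
    b_img, b_lab = augment(img, lab, cfg, seed=77)
    np.testing.assert_array_equal(a_img, b_img)
    np.testing.assert_array_equal(a_lab, b_lab)
    c_img, _ = augment(img, lab, cfg, seed=78)
    assert a_img.shape != c_img.shape or not np.array_equal(a_img, c_img)


def test_spatial_transforms_keep_image_and_labels_aligned(rng):
    img = np.zeros((8, 8, 8))
    img[2:5, 3:6, 1:4] = 1.0
    lab = (img > 0.5).astype(np.uint8)
    for seed in range(5):
        cfg = AugmentConfig(p=1.0, transforms=("flip", "rotation"))
        out_img, out_lab = augment(img, lab, cfg, seed=seed)
        np.testing.assert_array_equal(out_img > 0.5, out_lab.astype(bool))


# --- checkpoint selection and decoding ------------------------------------

def test_best_epoch_argmax_with_earlier_tie():
    assert select_best_epoch([0.2, 0.9, 0.7]) == 2
    assert select_best_epoch([0.5, 0.9, 0.9]) == 2


def test_one_hot_probabilities_decode_exactly(rng):
    labels = rng.integers(0, 3, size=(5, 5, 5)).astype(np.uint8)
    probs = np.zeros((3, 5, 5, 5))
    for c in range(3):
        probs[c] = labels == c
    pm = ProbabilityMap(probs, (1.5, 1.5, 2.0))
    np.testing.assert_array_equal(probabilities_to_labels(pm).labels, labels)


def test_uniform_probabilities_decode_to_background():
    pm = ProbabilityMap(np.full((3, 4, 4, 4), 1 / 3), (1, 1, 1))
    assert np.all(probabilities_to_labels(pm).labels == 0)


def test_argmax_agrees_with_brute_force(rng):
    probs = rng.random((3, 6, 6, 6))
    probs /= probs.sum(axis=0, keepdims=True)
    decoded = probabilities_to_labels(ProbabilityMap(probs, (1, 1, 1))).labels
    for z in range(6):
        for y in range(6):
            for x in range(6):
                assert decoded[z, y, x] == int(np.argmax(probs[:, z, y, x]))


def test_channel_count_must_match_scheme():
    pm = ProbabilityMap(np.full((4, 2, 2, 2), 0.25), (1, 1, 1))
    with pytest.raises(ParameterError):
        probabilities_to_labels(pm, ClassScheme.model_output())


# --- sliding-window inference ---------------------------------------------

@pytest.fixture(scope="module")
def micro_net():
    """A minimal valid config: token edge 4 with one decoding stage."""
    cfg = NetworkConfig(
        patch_size=(8, 8, 8), token_patch=4, blocks=2, hidden=8, ffn=16,
        heads=2, decoding_stages=1, decoder_channels=(4, 2), seed=0,
    )
    return build_network(cfg)


def test_window_probabilities_sum_to_one(micro_net, rng):
    vol = rng.random((12, 10, 8), dtype=np.float32)
    probs = sliding_window_probabilities(micro_net, vol)
    assert probs.shape == (3, 12, 10, 8)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)


def test_single_patch_volume_equals_direct_forward(micro_net, rng):
    vol = rng.random((8, 8, 8), dtype=np.float32)
    probs = sliding_window_probabilities(micro_net, vol)
    micro_net.eval()
    with no_grad():
        logits = micro_net(Tensor(vol[None])).data.astype(np.float64)
    e = np.exp(logits - logits.max(axis=0, keepdims=True))
    np.testing.assert_allclose(probs, e / e.sum(axis=0, keepdims=True), atol=1e-6)


def test_smaller_than_patch_volume_is_padded_and_cropped(micro_net, rng):
    vol = rng.random((5, 6, 7), dtype=np.float32)
    probs = sliding_window_probabilities(micro_net, vol)
    assert probs.shape == (3, 5, 6, 7)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)


def test_phase_schemes_collapse_onto_network_channels():
    from renovol.nn import map_labels_to_network_classes

    post = np.array([[[0, 1, 2, 3]]], dtype=np.uint8)
    mapped = map_labels_to_network_classes(post, ClassScheme.post_contrast())
    np.testing.assert_array_equal(mapped, [[[0, 1, 2, 0]]])  # pelvis-fat -> background

    pre = np.array([[[0, 1, 2]]], dtype=np.uint8)
    mapped = map_labels_to_network_classes(pre, ClassScheme.pre_contrast())
    np.testing.assert_array_equal(mapped, [[[0, 1, 0]]])  # parenchyma -> channel 1
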