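"""Detection phase: modality preparation, backbones, fusion mechanisms,
classification and training contracts."""

import numpy as np
import pytest

from histodiff._nn import Tensor
from histodiff.denoiser import DenoiserConfig, build_denoiser
from histodiff.diffusion import linear_schedule
from histodiff.fusion import (ABLATION_SCENARIOS, ClassifierHead, DetectorTrainSettings,
                              FusionConfig, FusionModule, MASK_PALETTE,
                              ModalityFeatures, build_backbone, build_detector,
                              classify, evaluate_detector, extract_features, fuse,
                              load_detector, prepare_modality_inputs, save_detector,
                              train_detector)
from histodiff.mask_codec import LabelMask
from histodiff.sampler import SamplerConfig, SegmentationResult, segment_batch
from histodiff.synthetic import FixtureSpec, generate_detection_dataset


def _seg_result(labels, K=3, seed=0):
    rng = np.random.default_rng(seed)
    return SegmentationResult(mask=LabelMask(labels=labels, K=K),
                              noise_map=rng.standard_normal(labels.shape + (K,)),
                              steps_used=1, seed=seed)


class TestPrepareModalities:
    def test_noise_channels_standardised(self, rng):
        labels = rng.integers(0, 3, (16, 16))
        seg = _seg_result(labels)
        img, mask_rgb, noise = prepare_modality_inputs(rng.random((16, 16, 3)), seg)
        assert img.shape == mask_rgb.shape == noise.shape == (16, 16, 3)
        assert np.allclose(noise.mean(axis=(0, 1)), 0.0, atol=1e-12)
        assert np.allclose(noise.std(axis=(0, 1)), 1.0, atol=1e-12)

    def test_constant_noise_channel_maps_to_zero(self, rng):
        labels = np.zeros((8, 8), dtype=int)
        seg = SegmentationResult(mask=LabelMask(labels=labels, K=3),
                                 noise_map=np.ones((8, 8, 3)), steps_used=1, seed=0)
        _, _, noise = prepare_modality_inputs(rng.random((8, 8, 3)), seg)
        assert np.all(noise == 0.0)

    def test_single_class_mask_renders_constant_palette(self, rng):
        labels = np.full((8, 8), 2, dtype=int)
        _, mask_rgb, _ = prepare_modality_inputs(rng.random((8, 8, 3)),
                                                 _seg_result(labels))
        assert np.all(mask_rgb == MASK_PALETTE[2])

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="size"):
            prepare_modality_inputs(rng.random((8, 8, 3)),
                                    _seg_result(np.zeros((4, 4), dtype=int)))


class TestExtractFeatures:
    def test_token_count_stride32(self, rng):
        ext = build_backbone("small", embed_dim=16, rng_seed=0, stages=5)
        feats = extract_features(ext, rng.random((128, 128, 3)))
        assert feats.tokens.shape == ((128 // 32) ** 2, 16)

    def test_deterministic_and_finite(self, rng):
        x = rng.random((16, 16, 3))
        a = extract_features(build_backbone("small", 8, 3), x)
        b = extract_features(build_backbone("small", 8, 3), x)
        assert np.array_equal(a.tokens, b.tokens)
        assert np.all(np.isfinite(a.tokens))

    def test_mbconv_backbone(self, rng):
        ext = build_backbone("mbconv", embed_dim=8, rng_seed=1, stages=3)
        feats = extract_features(ext, rng.random((16, 16, 3)), "noise")
        assert feats.tokens.shape == (4, 8) and feats.modality_tag == "noise"

    def test_indivisible_size_rejected(self, rng):
        ext = build_backbone("small", 8, 0, stages=3)
        with pytest.raises(ValueError, match="stride"):
            extract_features(ext, rng.random((12, 12, 3)))


def _bundles(rng, L=4, D=8):
    return [ModalityFeatures(tokens=rng.standard_normal((L, D)), modality_tag=m)
            for m in ("image", "mask", "noise")]


class TestFuse:
    def test_concat_dimension(self, rng):
        cfg = FusionConfig(mode="concat", embed_dim=8, heads=2)
        out = fuse(_bundles(rng), cfg, FusionModule(cfg, 0))
        assert out.shape == (24,)

    @pytest.mark.parametrize("mode", ["concat", "self_attention", "cross_attention",
                                      "transformer_decoder"])
    def test_all_modes_finite_fixed_dim(self, rng, mode):
        cfg = FusionConfig(mode=mode, embed_dim=8, heads=2)
        out = fuse(_bundles(rng), cfg, FusionModule(cfg, 1))
        assert out.shape == (cfg.fused_dim,) and np.all(np.isfinite(out))

    def test_decoder_keeps_query_token_count(self, rng):
        cfg = FusionConfig(mode="transformer_decoder", embed_dim=8, heads=2)
        module = FusionModule(cfg, 2)
        q = Tensor(rng.standard_normal((1, 5, 8)))
        mem = Tensor(rng.standard_normal((1, 7, 8)))
        out = module.decoder_layers[0](q, mem)
        assert out.shape == (1, 5, 8)

    def test_memory_permutation_invariance_without_positions(self, rng):
        cfg = FusionConfig(mode="transformer_decoder", embed_dim=8, heads=2,
                           positional_encoding=False)
        module = FusionModule(cfg, 3)
        feats = _bundles(rng)
        out = fuse(feats, cfg, module)
        perm = rng.permutation(feats[1].tokens.shape[0])
        feats_p = [feats[0],
                   ModalityFeatures(tokens=feats[1].tokens[perm], modality_tag="mask"),
                   feats[2]]
        assert np.allclose(out, fuse(feats_p, cfg, module), atol=1e-10)
        # with positional encodings the permutation is visible
        cfg_pos = FusionConfig(mode="transformer_decoder", embed_dim=8, heads=2)
        module_pos = FusionModule(cfg_pos, 3)
        a = fuse(feats, cfg_pos, module_pos)
        b = fuse(feats_p, cfg_pos, module_pos)
        assert not np.allclose(a, b)

    def test_missing_modality_rejected(self, rng):
        cfg = FusionConfig(mode="concat", embed_dim=8, heads=2)
        with pytest.raises(ValueError, match="missing"):
            fuse(_bundles(rng)[:1], cfg, FusionModule(cfg, 0))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            FusionConfig(embed_dim=8, heads=3)
        with pytest.raises(ValueError, match="image"):
            FusionConfig(modalities=("mask", "noise"))
        with pytest.raises(ValueError, match="two"):
            FusionConfig(mode="cross_attention", modalities=("image",))


class TestClassify:
    def _head(self, w=None):
        head = ClassifierHead(2, np.random.default_rng(0))
        head.fc.w.data = np.zeros((2, 2)) if w is None else np.asarray(w, float)
        head.fc.b.data = np.zeros(2)
        return head

    def test_symmetric_logits_hit_threshold(self):
        res = classify(np.ones(2), self._head())
        assert res.score == pytest.approx(0.5) and res.label == "cancer"

    def test_saturation(self):
        res = classify(np.array([1.0, 0.0]), self._head([[0.0, 50.0], [0.0, 0.0]]))
        assert res.score > 0.999 and res.label == "cancer"

    def test_strict_threshold_one(self):
        res = classify(np.ones(2), self._head(), threshold=1.0)
        assert res.label == "normal"


@pytest.fixture(scope="module")
def tiny_setup():
    """Untrained tiny segmenter + small detection set (8×8 patches)."""
    spec = FixtureSpec(size=8, K=3, n=20, cancer_fraction=0.5, seed=3,
                       blob_radius=(2.0, 3.0))
    data = generate_detection_dataset(spec)
    sched = linear_schedule(4, 0.1, 0.3)
    net = build_denoiser(DenoiserConfig(K=3, base_channels=8, depth=1), 0)
    cfg = SamplerConfig(schedule=sched, inference_steps=2, variance_mode="zero")
    segs = segment_batch(net, [p.image for p, _ in data], cfg, rng_seed=1)
    return net, data, segs


class TestDetectorTraining:
    def test_segmenter_is_frozen(self, tiny_setup):
        net, data, segs = tiny_setup
        before = [p.data.copy() for p in net.parameters()]
        detector = build_detector(FusionConfig(embed_dim=8, heads=2), 0, stages=2)
        train_detector(data, segs, detector,
                       DetectorTrainSettings(epochs=2, batch_size=8), rng_seed=0)
        for p, b in zip(net.parameters(), before):
            assert np.array_equal(p.data, b)

    def test_metrics_trace_deterministic(self, tiny_setup):
        _, data, segs = tiny_setup
        traces = []
        for _ in range(2):
            detector = build_detector(FusionConfig(embed_dim=8, heads=2), 4, stages=2)
            _, trace = train_detector(data, segs, detector,
                                      DetectorTrainSettings(epochs=3, batch_size=8),
                                      rng_seed=9)
            traces.append(trace)
        assert traces[0] == traces[1]

    def test_bad_label_rejected(self, tiny_setup):
        _, data, segs = tiny_setup
        bad = [(data[0][0], "maybe")]
        detector = build_detector(FusionConfig(embed_dim=8, heads=2), 0, stages=2)
        with pytest.raises(ValueError, match="label"):
            train_detector(bad, segs[:1], detector, rng_seed=0)

    def test_checkpoint_round_trip(self, tiny_setup, tmp_path):
        _, data, segs = tiny_setup
        detector = build_detector(FusionConfig(embed_dim=8, heads=2), 7, stages=2)
        detector, _ = train_detector(data, segs, detector,
                                     DetectorTrainSettings(epochs=1, batch_size=8),
                                     rng_seed=2)
        scores_a, _, _ = evaluate_detector(detector, data, segs)
        save_detector(tmp_path / "det.npz", detector, stages=2)
        again = load_detector(tmp_path / "det.npz")
        scores_b, _, _ = evaluate_detector(again, data, segs)
        assert np.allclose(scores_a, scores_b)


def test_mask_signal_lifts_fusion_over_image_only():
    """On a texture-only task (identical class colours) with ground-truth
    masks standing in for the frozen segmenter's output, three-modality
    decoder fusion is at least as accurate as the image-only baseline
    (margin >= 0 summed over 3 seeded repeats)."""
    spec = FixtureSpec(size=8, K=3, n=60, cancer_fraction=0.5, seed=6,
                       texture_only=True, noise_sd=0.02, blob_radius=(2.0, 3.0))
    data = generate_detection_dataset(spec)
    rng = np.random.default_rng(0)
    segs = [_seg_result(p.mask.labels, seed=i) for i, (p, _) in enumerate(data)]
    tr, te = list(zip(data[:40], segs[:40])), list(zip(data[40:], segs[40:]))
    margins = []
    for rep in range(3):
        accs = {}
        for name, cfg in (("image", FusionConfig(mode="concat", modalities=("image",),
                                                 embed_dim=8, heads=2)),
                          ("three", FusionConfig(mode="transformer_decoder",
                                                 embed_dim=8, heads=2))):
            det = build_detector(cfg, 100 + rep, stages=2)
            det, _ = train_detector([d for d, _ in tr], [s for _, s in tr], det,
                                    DetectorTrainSettings(epochs=8, batch_size=16),
                                    rng_seed=rep)
            _, _, acc = evaluate_detector(det, [d for d, _ in te], [s for _, s in te])
            accs[name] = acc
        margins.append(accs["three"] - accs["image"])
    assert sum(margins) >= 0.0


def test_ablation_scenarios_cover_required_grid():
    modes = {m for _, m, _ in ABLATION_SCENARIOS}
    assert modes == {"concat", "self_attention", "cross_attention", "transformer_decoder"}
    sizes = {len(mods) for _, _, mods in ABLATION_SCENARIOS}
    assert {1, 2, 3} <= sizes
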