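"""Breast-mask post-processing, vertical split, and segmenter training."""

import numpy as np
import pytest

from bpequant.breast_seg import (
    EmptyMaskError,
    ProbabilityMap,
    fallback_segmenter,
    postprocess_mask,
    predict_probability,
    split_breasts,
    train_segmenter,
)
from scipy import ndimage


def flood_fill_components_oracle(binary):
    """4/8-neighbour component labeling by explicit BFS (8-connectivity)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (0 <= nr < h and 0 <= nc < w and binary[nr, nc]
                                    and not seen[nr, nc]):
                                seen[nr, nc] = True
                                stack.append((nr, nc))
                comps.append(comp)
    return comps


def test_uniform_map_above_threshold_gives_full_mask():
    prob = ProbabilityMap(np.full((10, 12), 0.3))
    assert postprocess_mask(prob, 0.25).all()


def test_largest_object_kept():
    prob = np.zeros((30, 30))
    prob[2:7, 2:12] = 0.9    # 50 pixels
    prob[10:30, 10:30] = 0.9  # 400 pixels
    mask = postprocess_mask(ProbabilityMap(prob), 0.25)
    assert mask.sum() == 400
    assert mask[15, 15] and not mask[3, 3]


def test_matches_flood_fill_oracle():
    rng = np.random.default_rng(12)
    prob = ndimage.gaussian_filter(rng.random((40, 40)), 2.0)
    binary = prob > 0.5
    if not binary.any():
        pytest.skip("degenerate draw")
    comps = flood_fill_components_oracle(binary)
    largest = max(comps, key=len)
    expected = np.zeros_like(binary)
    for r, c in largest:
        expected[r, c] = True
    expected = ndimage.binary_fill_holes(expected)
    np.testing.assert_array_equal(postprocess_mask(prob, 0.5), expected)


def test_holes_are_filled():
    prob = np.zeros((20, 20))
    prob[5:15, 5:15] = 0.9
    prob[9:11, 9:11] = 0.0  # hole
    mask = postprocess_mask(ProbabilityMap(prob), 0.25)
    assert mask[10, 10]


def test_no_pixel_above_threshold_raises():
    with pytest.raises(EmptyMaskError):
        postprocess_mask(ProbabilityMap(np.full((5, 5), 0.1)), 0.25)


def test_split_at_bounding_box_centre():
    mask = np.zeros((6, 40), dtype=bool)
    mask[:, 10:30] = True  # columns 10..29
    masks = split_breasts(mask, affected_side="left")
    assert masks.split_column == 20
    assert masks.affected[:, 10:20].all() and not masks.affected[:, 20:].any()
    assert masks.unaffected[:, 20:30].all()


def test_split_is_a_partition_and_labels_follow_side():
    rng = np.random.default_rng(3)
    mask = np.zeros((20, 50), dtype=bool)
    mask[4:16, 5:45] = rng.random((12, 40)) > 0.3
    mask[10, 5:45] = True  # keep it one component-ish band
    m = split_breasts(mask, affected_side="right")
    assert ((m.affected | m.unaffected) == m.both).all()
    assert not (m.affected & m.unaffected).any()
    cols_a = np.nonzero(m.affected.any(axis=0))[0]
    assert cols_a.min() >= m.split_column  # right side


def test_split_unknown_side_labels_by_position():
    mask = np.zeros((4, 10), dtype=bool)
    mask[:, 2:8] = True
    with pytest.warns(UserWarning):
        m = split_breasts(mask, affected_side="unknown")
    assert not m.sides_labeled


def test_training_loss_decreases_and_is_deterministic():
    rng = np.random.default_rng(7)
    pairs = []
    for _ in range(8):  # blob images with their thresholded masks
        img = ndimage.gaussian_filter(rng.random((64, 64)), 4.0)
        mask = img > np.quantile(img, 0.6)
        pairs.append((img, mask))
    seg1 = train_segmenter(pairs, epochs_max=4, seed=1, input_shape=(64, 64))
    seg2 = train_segmenter(pairs, epochs_max=4, seed=1, input_shape=(64, 64))
    assert seg1.losses[-1] < seg1.losses[0]
    assert seg1.final_loss == seg2.final_loss
    prob = predict_probability(seg1, pairs[0][0])
    assert prob.data.shape == (64, 64)
    assert (prob.data >= 0).all() and (prob.data <= 1).all()


def test_training_warns_on_empty_masks_and_few_pairs():
    img = np.random.default_rng(0).random((32, 32))
    with pytest.warns(UserWarning):
        train_segmenter([(img, img > 0.5)], epochs_max=1, seed=0, input_shape=(32, 32))
    with pytest.raises(ValueError):
        train_segmenter([(img, np.zeros((32, 32), dtype=bool))], epochs_max=1,
                        seed=0, input_shape=(32, 32))


def test_predict_handles_constant_zero_image(segmenter):
    prob = predict_probability(segmenter, np.zeros((128, 128)))
    assert prob.data.shape == (128, 128)
    assert (prob.data >= 0).all() and (prob.data <= 1).all()


def test_trained_probabilities_higher_inside_breast(segmenter, holdout_cohort):
    from bpequant.projection import project
    from bpequant.volumes import subtract

    study, truth = holdout_cohort[0]
    mip = project(subtract(study, 2), "MIP")
    prob = predict_probability(segmenter, mip).data
    tm = truth.breast_projection_mask()
    assert prob[tm].mean() > prob[~tm].mean()


def test_fallback_segmenter_runs_untrained(lesion_phantom):
    from bpequant.projection import project
    from bpequant.volumes import subtract

    _, study, truth = lesion_phantom
    mip = project(subtract(study, 2), "MIP")
    mask = postprocess_mask(fallback_segmenter(mip), 0.25)
    tm = truth.breast_projection_mask()
    # convenience route only: the mask must at least lie inside the breasts
    assert (mask & tm).sum() / mask.sum() > 0.9
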