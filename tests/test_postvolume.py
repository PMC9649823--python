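"""Connected components, kidney selection and voxel-count volumetry."""
import warnings

import numpy as np
import pytest

from renovol.errors import SchemeViolationError
from renovol.imaging import ClassScheme, LabelMap
from renovol.postvolume import (
    extract_components,
    postprocess_labels,
    select_kidney_components,
    voxel_count_volume,
)


def brute_force_components(mask, connectivity=26):
    """Flood-fill oracle, independent of scipy labelling."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        stack, comp = [idx], []
        seen[idx] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= c < s for c, s in zip(nb, mask.shape)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(sorted(comp))
    return sorted(comps, key=len, reverse=True)


def test_two_separated_cubes():
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[1:4, 1:4, 1:4] = True     # 27 voxels
    mask[8:10, 8:10, 8:10] = True  # 8 voxels
    cs = extract_components(mask)
    assert [c.voxel_count for c in cs.components] == [27, 8]


def test_empty_and_single_voxel_masks():
    assert len(extract_components(np.zeros((4, 4, 4), dtype=bool))) == 0
    single = np.zeros((4, 4, 4), dtype=bool)
    single[2, 1, 3] = True
    cs = extract_components(single)
    assert len(cs) == 1 and cs.components[0].voxel_count == 1


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_components_agree_with_flood_fill_oracle(connectivity, rng):
    for _ in range(5):
        mask = rng.random((8, 8, 8)) < 0.2
        ours = extract_components(mask, connectivity=connectivity)
        oracle = brute_force_components(mask, connectivity)
        assert sorted(c.voxel_count for c in ours.components) == sorted(len(c) for c in oracle)
        # component membership identical, not just the counts
        ours_sets = sorted(
            sorted(map(tuple, np.argwhere(ours.label_grid == c.id))) for c in ours.components
        )
        assert ours_sets == sorted(oracle)


def test_kidneys_survive_noise_speck_removal(post_phantom):
    _, gt = post_phantom
    mask = gt.labels.parenchyma_mask().copy()
    true_count = int(mask.sum())
    rng = np.random.default_rng(0)
    for corner in [(2, 2, 2), (2, 90, 2), (60, 2, 2)]:  # 3 specks <= 10 voxels
        z, y, x = corner
        speck = rng.random((2, 2, 2)) < 0.9
        mask[z : z + 2, y : y + 2, x : x + 2] |= speck
    cs = extract_components(mask, gt.labels.spacing)
    kept = select_kidney_components(cs)
    assert len(kept) == 2
    assert sum(c.voxel_count for c in kept.components) == true_count


def test_single_component_with_expected_two_warns():
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[2:5, 2:5, 2:5] = True
    cs = extract_components(mask)
    with pytest.warns(UserWarning):
        kept = select_kidney_components(cs, expected=2)
    assert len(kept) == 1


def test_clean_two_component_input_is_identity(post_phantom):
    _, gt = post_phantom
    mask = gt.labels.parenchyma_mask()
    cs = extract_components(mask, gt.labels.spacing)
    kept = select_kidney_components(cs)
    np.testing.assert_array_equal(kept.mask(), mask)


def test_selection_orders_components_cranial_then_left():
    mask = np.zeros((20, 20, 40), dtype=bool)
    mask[12:15, 5:8, 30:34] = True  # caudal, right
    mask[2:5, 5:8, 2:6] = True      # cranial, left
    kept = select_kidney_components(extract_components(mask, (1.0, 1.0, 1.0)))
    z0 = kept.components[0].centroid_mm[2]
    z1 = kept.components[1].centroid_mm[2]
    assert z0 < z1


def test_min_separation_prevents_fragment_pairs():
    mask = np.zeros((10, 10, 30), dtype=bool)
    mask[3:6, 3:6, 2:7] = True    # fragment A
    mask[3:6, 3:6, 9:13] = True   # fragment B, ~7 mm away from A
    mask[3:6, 3:6, 24:28] = True  # the other kidney, far away
    cs = extract_components(mask, (1.0, 1.0, 1.0))
    assert len(cs) == 3
    kept = select_kidney_components(cs, expected=2, min_separation_mm=15.0)
    xs = sorted(c.centroid_mm[0] for c in kept.components)
    assert xs[1] - xs[0] >= 15.0


# --- voxel-count volume ---------------------------------------------------

def test_thousand_voxels_at_default_spacing_is_4p5_cm3(post_scheme):
    lab = np.zeros((10, 10, 20), dtype=np.uint8)
    lab.ravel()[:1000] = 1
    lm = LabelMap(lab, (1.5, 1.5, 2.0), post_scheme)
    res = voxel_count_volume(lm, classes={1})
    assert res.volumes_cm3["selection"] == pytest.approx(1000 * 4.5 / 1000.0, abs=1e-12)


def test_empty_class_selection_is_zero(post_scheme):
    lm = LabelMap(np.zeros((4, 4, 4), dtype=np.uint8), (1.5, 1.5, 2.0), post_scheme)
    assert voxel_count_volume(lm, classes={2}).volumes_cm3["selection"] == 0.0


def test_unknown_class_id_rejected(post_scheme):
    lm = LabelMap(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1), post_scheme)
    with pytest.raises(SchemeViolationError):
        voxel_count_volume(lm, classes={9})


def test_phantom_volume_within_three_percent_of_analytic(post_phantom):
    _, gt = post_phantom
    res = voxel_count_volume(gt.labels)
    assert res.volumes_cm3["parenchyma"] == pytest.approx(
        gt.analytic_volumes_cm3["parenchyma"], rel=0.03
    )
    assert res.volumes_cm3["parenchyma"] == pytest.approx(
        res.volumes_cm3["cortex"] + res.volumes_cm3["medulla"], abs=1e-9
    )


def test_volume_invariant_under_axis_permutation(post_phantom):
    _, gt = post_phantom
    lab = gt.labels
    permuted = LabelMap(
        lab.labels.transpose(2, 0, 1),  # (x, z, y) grid
        (lab.spacing[1], lab.spacing[2], lab.spacing[0]),
        lab.scheme,
    )
    a = voxel_count_volume(lab).volumes_cm3
    b = voxel_count_volume(permuted).volumes_cm3
    for key in a:
        assert a[key] == pytest.approx(b[key], abs=1e-9)


def test_postprocessing_never_increases_volume(post_phantom):
    _, gt = post_phantom
    noisy = gt.labels.labels.copy()
    noisy[0:2, 0:2, 0:2] = 1  # inject a corner speck
    lm = LabelMap(noisy, gt.labels.spacing, gt.labels.scheme)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cleaned = postprocess_labels(lm)
    before = voxel_count_volume(lm).volumes_cm3["total"]
    after = voxel_count_volume(cleaned).volumes_cm3["total"]
    assert after <= before
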