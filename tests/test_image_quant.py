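"""Segmentation and per-cell quantification against synthetic ground truth."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from appscreen.errors import InputError
from appscreen.image_quant import (QuantConfig, WellImageStack, quantify_well,
                                   segment_cells, segment_nuclei, segment_well)
from appscreen.synth_microscopy import (CellGroundTruth, ImageSimParams,
                                        render_well, sample_well_layout)

NOISELESS = dict(background=(0.0, 0.0, 0.0), noise_sd=(0.0, 0.0, 0.0))


def _disc_labels(shape, centers, radius):
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.indices(shape)
    for i, (r, c) in enumerate(centers, start=1):
        labels[(rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2] = i
    return labels


def test_blank_image_has_zero_nuclei():
    assert segment_nuclei(np.zeros((64, 64))).max() == 0


def test_empty_image_rejected():
    with pytest.raises(InputError):
        segment_nuclei(np.zeros((0, 0)))


def test_noiseless_fifty_cells_counted_exactly_with_centroids():
    params = ImageSimParams(image_size=(512, 512), **NOISELESS, seed=8)
    cells = sample_well_layout(50, params)
    stack, _ = render_well(params, cells)
    labels = segment_nuclei(stack.hoechst)
    assert labels.max() == 50
    found = np.array(ndi.center_of_mass(
        labels > 0, labels, index=range(1, 51)))
    truth = np.array([[c.center_row, c.center_col] for c in cells])
    # match each truth centre to its nearest segmented centroid
    d = np.sqrt(((truth[:, None, :] - found[None, :, :]) ** 2).sum(-1))
    assert d.min(axis=1).max() <= 1.0


def test_tangent_nuclei_split_by_watershed():
    params = ImageSimParams(image_size=(128, 128), **NOISELESS,
                            overlap_allowed=True)
    r = params.nucleus_radius
    cells = [
        CellGroundTruth(1, 64.0, 50.0, r, params.cytoplasm_radius, 10, 10),
        CellGroundTruth(2, 64.0, 50.0 + 2 * r, r, params.cytoplasm_radius,
                        10, 10),
    ]
    stack, _ = render_well(params, cells)
    labels = segment_nuclei(stack.hoechst)
    assert labels.max() == 2


def test_isolated_cytoplasm_is_ring_of_configured_width():
    labels = _disc_labels((96, 96), [(48, 48)], radius=8)
    cells, cyto = segment_cells(labels, ring_width=4, inner_margin=1)
    # oracle: EDT distance from the nucleus mask
    dist = ndi.distance_transform_edt(labels == 0)
    ring = cyto > 0
    assert ring.any()
    assert dist[ring].min() > 0
    assert dist[ring].max() <= 5.0  # inner_margin + ring_width
    assert not (ring & (dist <= 1.0)).any()  # guard band respected
    assert np.array_equal(np.unique(cells[ring]), [1])


def test_adjacent_cells_partition_at_equidistant_boundary():
    centers = [(48, 30), (48, 46)]  # closer than 2 * (margin + width)
    labels = _disc_labels((96, 96), centers, radius=6)
    _, cyto = segment_cells(labels, ring_width=6, inner_margin=1)
    d1 = ndi.distance_transform_edt(labels != 1)
    d2 = ndi.distance_transform_edt(labels != 2)
    # nearest-seed oracle: each pixel belongs to the closer nucleus
    assert (d1[cyto == 1] <= d2[cyto == 1]).all()
    assert (d2[cyto == 2] <= d1[cyto == 2]).all()


def test_zero_ring_width_warns_and_gives_empty_cytoplasm():
    labels = _disc_labels((64, 64), [(32, 32)], radius=6)
    with pytest.warns(UserWarning, match="ring_width"):
        _, cyto = segment_cells(labels, ring_width=0)
    assert cyto.max() == 0


@pytest.fixture(scope="module")
def noiseless_well():
    params = ImageSimParams(image_size=(512, 512), **NOISELESS, seed=31)
    cells = sample_well_layout(60, params)
    stack, _ = render_well(params, cells)
    return params, cells, stack


def _match_measurements(cells, seg, measurements):
    pairs = []
    for cell in cells:
        lab = seg.nucleus_labels[int(round(cell.center_row)),
                                 int(round(cell.center_col))]
        row = measurements[measurements["cell_id"] == lab]
        if lab > 0 and len(row) == 1:
            pairs.append((cell, row.iloc[0]))
    return pairs


def test_noiseless_quantification_recovers_truth_exactly(noiseless_well):
    _, cells, stack = noiseless_well
    seg = segment_well(stack)
    record, meas = quantify_well(stack, seg)
    assert record["cell_count"] == len(cells)
    pairs = _match_measurements(cells, seg, meas)
    assert len(pairs) == len(cells)
    for cell, row in pairs:
        assert row["mcherry_mean"] == pytest.approx(
            cell.true_mcherry_mean, rel=1e-9)
        assert row["yfp_mean"] == pytest.approx(
            cell.true_yfp_mean, rel=1e-9)
    assert record["mcherry_mean"] == pytest.approx(
        np.mean([c.true_mcherry_mean for c in cells]), rel=1e-9)


def test_uniform_background_shift_leaves_means_unchanged(noiseless_well):
    _, _, stack = noiseless_well
    seg = segment_well(stack)
    base, _ = quantify_well(stack, seg)
    shifted = WellImageStack(
        hoechst=stack.hoechst, yfp=stack.yfp + 37.0,
        mcherry=stack.mcherry + 37.0, well_id=stack.well_id)
    rec, _ = quantify_well(shifted, seg)
    assert rec["mcherry_mean"] == pytest.approx(base["mcherry_mean"], rel=1e-9)
    assert rec["yfp_mean"] == pytest.approx(base["yfp_mean"], rel=1e-9)


def test_channel_scaling_scales_means(noiseless_well):
    _, _, stack = noiseless_well
    seg = segment_well(stack)
    base, _ = quantify_well(stack, seg)
    scaled = WellImageStack(
        hoechst=stack.hoechst, yfp=stack.yfp, mcherry=stack.mcherry * 3.0,
        well_id=stack.well_id)
    rec, _ = quantify_well(scaled, seg)
    assert rec["mcherry_mean"] == pytest.approx(
        3.0 * base["mcherry_mean"], rel=1e-9)


def test_zero_cell_well_flagged_not_raised():
    stack = WellImageStack(hoechst=np.zeros((64, 64)),
                           yfp=np.zeros((64, 64)),
                           mcherry=np.zeros((64, 64)), well_id="empty")
    seg = segment_well(stack)
    record, meas = quantify_well(stack, seg)
    assert record["cell_count"] == 0
    assert np.isnan(record["mcherry_mean"])
    assert meas.empty


def test_default_noise_single_well_accuracy():
    # one full-scale well at the default noise model; the 20-well error
    # bounds run in the acceptance suite
    params = ImageSimParams(seed=17)
    cells = sample_well_layout(400, params)
    stack, _ = render_well(params, cells)
    seg = segment_well(stack)
    record, meas = quantify_well(stack, seg)
    assert abs(record["cell_count"] - len(cells)) / len(cells) <= 0.05
    pairs = _match_measurements(cells, seg, meas)
    rel_err = [abs(row["mcherry_mean"] - c.true_mcherry_mean)
               / c.true_mcherry_mean for c, row in pairs]
    assert np.mean(rel_err) <= 0.02
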