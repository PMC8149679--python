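"""Feature-ablation maps: identities, reconstruction oracle, overlap statistics."""

import numpy as np
import pytest

from vqradiomics.phantom import LabeledVolume
from vqradiomics.pipeline import preprocess_volume
from vqradiomics.regions import (
    _background_latent_mask,
    ablate_codeword,
    aggregate_responsible_regions,
    find_background_vector,
    quantify_overlap,
)
from vqradiomics.stats import dunn_test
from vqradiomics.vq import QuantizedLatent
from vqradiomics.regions import ResponsibleRegionMap


def test_background_latent_mask_strict_majority():
    fg = np.zeros((1, 4, 4), dtype=bool)
    fg[0, :2, :2] = True  # one latent cell fully foreground at reduction 2
    fg[0, 2, 2] = True  # another cell only 1/4 foreground
    mask = _background_latent_mask(fg, reduction=2)
    # cell (0,0): 0% background -> not background; cell (1,1): 75% -> background
    assert mask[0, 0, 0] == np.False_
    assert mask[0, 1, 1] == np.True_
    assert mask[0, 0, 1] == np.True_ and mask[0, 1, 0] == np.True_


def test_background_vector_on_pure_background(tiny_net):
    """An all-background volume maps every latent cell to one codeword."""
    image = np.zeros((4, 32, 32, 2), dtype=np.float32)
    image[:, 12:20, 12:20, :] = 1.0  # small foreground so preprocessing is sane
    vol = LabeledVolume(image=image, labels=None, grade=None, volume_id="bgv")
    bg = find_background_vector([vol], tiny_net)
    assert 0 <= bg.index < tiny_net.codebook.K
    assert bg.support_fraction > 0.5


def test_background_codewords_cover_modal_vector(tiny_net):
    """On a mostly-background volume, the codewords flagged as background
    include the modal background vector, and only used codewords appear."""
    from vqradiomics.regions import background_codewords

    image = np.zeros((4, 32, 32, 2), dtype=np.float32)
    image[:, 12:20, 12:20, :] = 1.0
    vol = LabeledVolume(image=image, labels=None, grade=None, volume_id="bgv")
    bg = find_background_vector([vol], tiny_net)
    flagged = background_codewords([vol], tiny_net)
    assert bg.index in flagged
    assert all(0 <= k < tiny_net.codebook.K for k in flagged)


def test_background_vector_requires_background(tiny_net):
    image = np.ones((4, 32, 32, 1), dtype=np.float32)
    vol = LabeledVolume(image=image, labels=None, grade=None, volume_id="full")
    with pytest.raises(ValueError):
        find_background_vector([vol], tiny_net)


def _quantized_grid(net, rng):
    idx = rng.integers(0, net.codebook.K, (16, 16))
    values = np.moveaxis(net.codebook.vectors[idx], -1, 0)
    return QuantizedLatent(indices=idx, values=values)


def test_ablation_zero_when_absent(tiny_net, rng):
    q = _quantized_grid(tiny_net, rng)
    absent = int(next(k for k in range(tiny_net.codebook.K)
                      if not np.any(q.indices == k))) if (
        len(np.unique(q.indices)) < tiny_net.codebook.K) else None
    if absent is None:
        q.indices[q.indices == 7] = 0
        q.values = np.moveaxis(tiny_net.codebook.vectors[q.indices], -1, 0)
        absent = 7
    m = ablate_codeword(q, absent, background=0, net=tiny_net)
    assert np.all(m.values == 0.0)


def test_ablation_zero_for_background_self_replacement(tiny_net, rng):
    q = _quantized_grid(tiny_net, rng)
    target = int(q.indices[0, 0])
    with pytest.warns(RuntimeWarning, match="background"):
        m = ablate_codeword(q, target, background=target, net=tiny_net)
    assert np.all(m.values == 0.0)


def test_ablation_matches_position_by_position_oracle(tiny_net, rng):
    """The map equals a brute-force reconstruction that rebuilds the replaced
    latent one position at a time."""
    q = _quantized_grid(tiny_net, rng)
    target = int(q.indices[0, 0])
    bg = int((target + 1) % tiny_net.codebook.K)
    m = ablate_codeword(q, target, background=bg, net=tiny_net, frozen_norm=False)

    rebuilt = q.values.copy()
    for i in range(q.indices.shape[0]):
        for j in range(q.indices.shape[1]):
            if q.indices[i, j] == target:
                rebuilt[:, i, j] = tiny_net.codebook.vectors[bg]
    logits = tiny_net.decode(q.values).logits
    logits2 = tiny_net.decode(rebuilt).logits
    expected = np.abs(logits - logits2).sum(axis=0)
    np.testing.assert_array_equal(m.values, expected)


def test_ablation_nonzero_when_present(tiny_net, rng):
    q = _quantized_grid(tiny_net, rng)
    target = int(q.indices[0, 0])
    bg = int((target + 1) % tiny_net.codebook.K)
    m = ablate_codeword(q, target, background=bg, net=tiny_net)
    assert m.values.max() > 0.0
    assert np.all(m.values >= 0.0)


def test_aggregation_is_additive(tiny_trained):
    net, volumes, _ = tiny_trained
    pre = preprocess_volume(volumes[0])
    q = net.quantize(net.encode(pre.images), count_usage=False)
    used = [int(k) for k in np.unique(q.indices)][:2]
    if len(used) < 2:
        pytest.skip("fewer than two codewords in use")
    bg = int(max(np.unique(q.indices)))
    both = aggregate_responsible_regions([pre], net, used, bg)[0]
    single = [aggregate_responsible_regions([pre], net, [k], bg)[0] for k in used]
    np.testing.assert_allclose(both.values, single[0].values + single[1].values,
                               rtol=1e-5, atol=1e-5)
    with pytest.raises(ValueError):
        aggregate_responsible_regions([pre], net, [], bg)


def test_standardized_map_flagged():
    m = ResponsibleRegionMap(values=np.arange(8.0).reshape(2, 2, 2), ablated=(1,))
    s = m.standardized()
    assert s.normalization == "per-patient-standardized"
    assert abs(s.values.mean()) < 1e-12


def test_quantify_overlap_uniform_map(tiny_phantoms):
    """A uniformly-one map sums to the label voxel counts."""
    vols = tiny_phantoms[:4]
    pres = [preprocess_volume(v) for v in vols]
    maps = [ResponsibleRegionMap(values=np.ones_like(p.labels, dtype=float),
                                 ablated=(0,)) for p in pres]
    stats = quantify_overlap(maps, pres)
    for row, p in zip(stats.sums.itertuples(), pres):
        assert row.NET == (p.labels == 1).sum()
        assert row.ED == (p.labels == 2).sum()
        assert row.ET == (p.labels == 3).sum()
    # absent labels are flagged with zero sums
    class1 = [p for p in pres if p.grade == 1]
    if class1:
        vid = class1[0].volume_id
        row = stats.sums[stats.sums.volume_id == vid].iloc[0]
        assert row["NET"] == 0.0 and bool(row["NET_absent"])


def test_quantify_overlap_rejects_standardized_maps(tiny_phantoms):
    pre = preprocess_volume(tiny_phantoms[0])
    m = ResponsibleRegionMap(values=np.ones_like(pre.labels, dtype=float),
                             ablated=(0,)).standardized()
    with pytest.raises(ValueError):
        quantify_overlap([m], [pre])


def test_dunn_matches_hand_computation():
    """Three small groups with a tie, ranked by hand."""
    groups = {
        "A": np.array([1.0, 2.0, 3.0]),
        "B": np.array([4.0, 5.0, 6.0]),
        "C": np.array([6.0, 8.0, 9.0]),
    }
    # joint ranks: 1,2,3 | 4,5,6.5 | 6.5,8,9  (tie at value 6)
    res = dunn_test(groups, adjust="none")
    assert res.mean_ranks["A"] == pytest.approx(2.0)
    assert res.mean_ranks["B"] == pytest.approx(31 / 6)
    assert res.mean_ranks["C"] == pytest.approx(47 / 6)
    n = 9
    tie_term = 2**3 - 2  # one group of two tied values
    var = n * (n + 1) / 12 - tie_term / (12 * (n - 1))
    se = np.sqrt(var * (1 / 3 + 1 / 3))
    z_ab = (2.0 - 31 / 6) / se
    assert res.z[("A", "B")] == pytest.approx(z_ab)
    from scipy.stats import norm
    assert res.p_raw[("A", "B")] == pytest.approx(2 * norm.sf(abs(z_ab)))
    # bonferroni adjustment multiplies by the number of pairs (3)
    res_b = dunn_test(groups, adjust="bonferroni")
    assert res_b.p_adjusted[("A", "B")] == pytest.approx(
        min(1.0, 3 * res.p_raw[("A", "B")]))
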