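"""Window/stripe partitioning and masked shifted attention, checked
against brute-force dense oracles."""

import numpy as np
import pytest

from crcformer.attention import (AttentionSpec, WindowMSA, partition,
                                 preroll_group_attention,
                                 shifted_equivalence_check)
from crcformer.tensor import Tensor, no_grad


def dense_attention_oracle(x, module):
    """Full (unwindowed) self-attention over all tokens with the module's
    weights — valid reference whenever one window covers the whole map."""
    b, h, w, c = x.shape
    heads, hd = module.spec.heads, module.head_dim
    tok = x.reshape(b, h * w, c).astype(np.float64)
    qkv = tok @ module.qkv.weight.data + module.qkv.bias.data
    q, k, v = np.split(qkv, 3, axis=-1)
    out = np.zeros_like(tok)
    coords = np.stack(np.meshgrid(np.arange(h), np.arange(w), indexing="ij"),
                      -1).reshape(-1, 2)
    wh, ww = module.part.tile
    dr = coords[:, None, 0] - coords[None, :, 0]
    dc = coords[:, None, 1] - coords[None, :, 1]
    bias = module.bias_table.data[(dr + wh - 1) * (2 * ww - 1) + dc + ww - 1]
    for hh in range(heads):
        sl = slice(hh * hd, (hh + 1) * hd)
        s = q[..., sl] @ k[..., sl].swapaxes(-1, -2) / np.sqrt(hd)
        s = s + bias[None, :, :, hh]
        p = np.exp(s - s.max(-1, keepdims=True))
        p /= p.sum(-1, keepdims=True)
        out[..., sl] = p @ v[..., sl]
    out = out @ module.proj.weight.data + module.proj.bias.data
    return out.reshape(b, h, w, c)


def test_partition_unshifted_small_windows():
    part = partition(4, 4, AttentionSpec("WS", 2, 0))
    assert len(part.groups) == 4
    assert all(len(g) == 4 for g in part.groups)
    assert part.mask.all()


def test_partition_horizontal_stripes():
    part = partition(4, 4, AttentionSpec("SH", 2, 0))
    assert [sorted(g) for g in part.groups] == [list(range(8)),
                                                list(range(8, 16))]


def test_partition_vertical_stripes_full_height():
    part = partition(4, 4, AttentionSpec("SV", 2, 0))
    cols = [{t % 4 for t in g} for g in part.groups]
    assert cols == [{0, 1}, {2, 3}]


def test_partition_rejects_bad_grid():
    with pytest.raises(ValueError):
        partition(0, 4, AttentionSpec("WS", 2))


def test_shifted_mask_matches_window_id_oracle():
    """Brute force: enumerate each token's pre-roll window id and check the
    mask admits exactly same-id pairs."""
    spec = AttentionSpec("WS", 2, 1)
    part = partition(4, 4, spec)
    assert len(part.groups) == 4
    region = part.region_ids.reshape(-1)
    for g, idx_row in enumerate(part.index):
        for a_pos, a_tok in enumerate(idx_row):
            for b_pos, b_tok in enumerate(idx_row):
                if a_tok < 0 or b_tok < 0:
                    continue
                expected = region[a_tok] == region[b_tok]
                assert part.mask[g, a_pos, b_pos] == expected


def test_partition_is_bijection_randomized(rng):
    for _ in range(50):
        h = int(rng.integers(1, 13))
        w = int(rng.integers(1, 13))
        window = int(rng.integers(1, 9))
        spec = AttentionSpec(str(rng.choice(["WB", "WS", "SH", "SV"])),
                             window, int(rng.integers(0, window)))
        part = partition(h, w, spec)
        tokens = part.index[part.index >= 0]
        assert np.array_equal(np.sort(tokens), np.arange(h * w))
        assert (part.inverse >= 0).all()
        # scatter(gather(x)) identity on a random map
        x = rng.standard_normal(h * w)
        gathered = np.where(part.index >= 0, x[part.index], 0.0)
        assert np.allclose(gathered.reshape(-1)[part.inverse], x)


def test_single_token_group_returns_value_projection(rng):
    module = WindowMSA(4, AttentionSpec("WS", 1, 0, heads=2), 1, 1,
                       rng=np.random.default_rng(0))
    x = rng.standard_normal((1, 1, 1, 4)).astype(np.float32)
    with no_grad():
        out = module(Tensor(x)).data
    qkv = x.reshape(1, 4) @ module.qkv.weight.data + module.qkv.bias.data
    v = qkv[:, 8:]
    expected = v @ module.proj.weight.data + module.proj.bias.data
    np.testing.assert_allclose(out.reshape(1, 4), expected, atol=1e-5)


def test_uniform_values_are_attention_fixed_point(rng):
    """If every token's value row equals v, attention returns (proj of) v."""
    module = WindowMSA(6, AttentionSpec("WB", 4, 0, heads=3), 4, 4,
                       rng=np.random.default_rng(1))
    # force V projection to a constant row regardless of input
    module.qkv.weight.data[:, 12:] = 0.0
    vrow = rng.standard_normal(6).astype(np.float32)
    module.qkv.bias.data[12:] = vrow
    x = rng.standard_normal((2, 4, 4, 6)).astype(np.float32)
    with no_grad():
        out = module(Tensor(x)).data
    expected = vrow @ module.proj.weight.data + module.proj.bias.data
    np.testing.assert_allclose(out, np.broadcast_to(expected, out.shape),
                               atol=1e-5)


@pytest.mark.parametrize("variant, window", [("WB", 4), ("SH", 4), ("SV", 4)])
def test_whole_map_window_equals_dense_attention(rng, variant, window):
    """A window/stripe covering the map is exactly full self-attention."""
    module = WindowMSA(8, AttentionSpec(variant, window, 0, heads=2), 4, 4,
                       rng=np.random.default_rng(2))
    module.bias_table.data = 0.1 * np.random.default_rng(3).standard_normal(
        module.bias_table.data.shape).astype(np.float32)
    x = rng.standard_normal((2, 4, 4, 8)).astype(np.float32)
    with no_grad():
        fast = module(Tensor(x)).data
    np.testing.assert_allclose(fast, dense_attention_oracle(x, module),
                               atol=1e-5)


@pytest.mark.parametrize("variant, window, shift, shape", [
    ("WS", 4, 0, (1, 8, 8, 4)),
    ("WS", 4, 2, (1, 8, 8, 4)),
    ("SH", 2, 1, (1, 8, 8, 4)),
    ("SV", 2, 1, (1, 8, 8, 4)),
    ("WB", 8, 4, (1, 8, 8, 4)),
    ("WS", 3, 1, (1, 7, 5, 4)),   # ragged extents
])
def test_shifted_equivalence(rng, variant, window, shift, shape):
    x = rng.standard_normal(shape)
    assert shifted_equivalence_check(x, AttentionSpec(variant, window, shift,
                                                      heads=2))


def test_shift_zero_equivalence_trivial(rng):
    x = rng.standard_normal((1, 6, 6, 4))
    assert shifted_equivalence_check(x, AttentionSpec("WS", 3, 0, heads=2))


def test_group_permutation_equivariance(rng):
    """Permuting tokens inside a window (with bias permuted accordingly)
    permutes the outputs: attention is a set operation within a group."""
    module = WindowMSA(4, AttentionSpec("WB", 4, 0, heads=2), 4, 4,
                       rng=np.random.default_rng(5))
    x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
    with no_grad():
        base = module(Tensor(x)).data.reshape(16, 4)
    # permute spatial tokens: with zero bias the module is equivariant
    perm = np.random.default_rng(6).permutation(16)
    xp = x.reshape(1, 16, 4)[:, perm].reshape(1, 4, 4, 4)
    with no_grad():
        out = module(Tensor(xp)).data.reshape(16, 4)
    np.testing.assert_allclose(out, base[perm], atol=1e-5)


def test_bounded_inputs_no_overflow(rng):
    module = WindowMSA(8, AttentionSpec("WS", 2, 1, heads=2), 8, 8,
                       rng=np.random.default_rng(7))
    x = (rng.random((1, 8, 8, 8)) * 2e3 - 1e3).astype(np.float32)
    with no_grad():
        out = module(Tensor(x)).data
    assert np.isfinite(out).all()


def test_channel_head_mismatch_rejected():
    with pytest.raises(ValueError, match="divisible"):
        WindowMSA(5, AttentionSpec("WS", 2, 0, heads=2), 4, 4)


def test_wrong_extent_rejected(rng):
    module = WindowMSA(4, AttentionSpec("WS", 2, 0, heads=2), 4, 4)
    with pytest.raises(ValueError, match="map"):
        module(Tensor(rng.standard_normal((1, 6, 6, 4))))
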