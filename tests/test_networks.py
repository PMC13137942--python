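"""Attention algebra, positional-embedding transfer, gated attention,
and the segmentation network's output contracts."""

import numpy as np
import pytest

from cspine import autodiff as ad
from cspine.networks import (GateParams, SegConfig, SegNet, ViTConfig,
                             ViTEncoder, gated_attention, load_encoder_state,
                             msa, resize_pos_embed, seg_forward)


# ---------------------------------------------------------------------------
# multi-head self-attention
# ---------------------------------------------------------------------------

def _loop_attention(Z, wq, wk, wv, wo, heads):
    """Brute-force per-head attention with explicit Python loops."""
    n, d = Z.shape
    dh = d // heads
    out = np.zeros((n, d))
    for h in range(heads):
        q = Z @ wq[:, h * dh:(h + 1) * dh]
        k = Z @ wk[:, h * dh:(h + 1) * dh]
        v = Z @ wv[:, h * dh:(h + 1) * dh]
        for i in range(n):
            scores = np.array([q[i] @ k[j] / np.sqrt(dh) for j in range(n)])
            e = np.exp(scores - scores.max())
            a = e / e.sum()
            out[i, h * dh:(h + 1) * dh] = sum(a[j] * v[j] for j in range(n))
    return out @ wo


def test_msa_hand_example_single_token_dim():
    """H=1, d=1, Z=[[1],[1]], identity projections: uniform attention
    averages identical values -> output [[1],[1]]."""
    Z = np.array([[1.0], [1.0]])
    one = np.array([[1.0]])
    out = msa(Z, one, one, one, one, heads=1)
    assert np.allclose(out, [[1.0], [1.0]])


def test_msa_zero_values_and_permutation_equivariance(rng):
    d, h, n = 8, 2, 5
    Z = rng.normal(size=(n, d)).astype(np.float32)
    wq, wk, wv, wo = (rng.normal(size=(d, d)).astype(np.float32)
                      for _ in range(4))
    assert np.allclose(msa(Z, wq, wk, np.zeros((d, d)), wo, heads=h), 0.0)

    perm = rng.permutation(n)
    out = msa(Z, wq, wk, wv, wo, heads=h)
    out_p = msa(Z[perm], wq, wk, wv, wo, heads=h)
    assert np.allclose(out_p, out[perm], atol=1e-5)


def test_msa_matches_loop_oracle(rng):
    d, h = 8, 4
    Z = rng.normal(size=(4, d))
    wq, wk, wv, wo = (rng.normal(size=(d, d)) for _ in range(4))
    ours = msa(Z, wq, wk, wv, wo, heads=h)
    brute = _loop_attention(Z, wq, wk, wv, wo, h)
    assert np.abs(ours - brute).max() < 1e-6

    with pytest.raises(ValueError):
        msa(Z, wq, wk, wv, wo, heads=3)


# ---------------------------------------------------------------------------
# positional embedding resize
# ---------------------------------------------------------------------------

def test_resize_pos_embed_identity_and_constant(rng):
    e = rng.normal(size=(4, 4, 4, 8)).astype(np.float32)
    assert np.array_equal(resize_pos_embed(e, (4, 4, 4)), e)
    const = np.full((3, 3, 3, 5), 2.5, dtype=np.float32)
    assert np.allclose(resize_pos_embed(const, (6, 5, 2)), 2.5)


def test_resize_pos_embed_linear_profile():
    """A linear-in-z embedding resized 6^3 -> 3^3 interpolates the line
    (align-corners sampling at z = 0, 2.5, 5)."""
    z = np.arange(6, dtype=np.float32)
    e = np.broadcast_to(z[None, None, :, None], (6, 6, 6, 1)).copy()
    out = resize_pos_embed(e, (3, 3, 3))
    assert np.allclose(out[0, 0, :, 0], [0.0, 2.5, 5.0], atol=1e-6)


# ---------------------------------------------------------------------------
# gated attention
# ---------------------------------------------------------------------------

def test_gated_attention_hand_arithmetic():
    """theta_x = theta_g = 1, b = 0, psi = 1, x = 1, g = -3:
    q = -2, ReLU -> 0, alpha = sigma(0) = 0.5, gated x = 0.5."""
    params = GateParams(theta_x=np.array([[1.0]]),
                        theta_g=np.array([[1.0]]),
                        b=np.array([0.0]), psi=np.array([1.0]))
    out = gated_attention(np.array([[1.0]]), np.array([[-3.0]]), params)
    assert out == pytest.approx(0.5)


def test_gated_attention_saturation_and_bounds(rng):
    x = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
    g = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
    base = GateParams(theta_x=rng.normal(size=(3, 2)),
                      theta_g=rng.normal(size=(3, 2)),
                      b=rng.normal(size=3), psi=rng.normal(size=3))
    out = gated_attention(x, g, base)
    assert np.all(np.abs(out) <= np.abs(x) + 1e-6)  # alpha in (0,1)

    hot = GateParams(base.theta_x, base.theta_g, base.b, base.psi,
                     psi_b=50.0)
    assert np.allclose(gated_attention(x, g, hot), x, atol=1e-4)
    cold = GateParams(base.theta_x, base.theta_g, base.b, base.psi,
                      psi_b=-50.0)
    assert np.allclose(gated_attention(x, g, cold), 0.0, atol=1e-4)

    with pytest.raises(ValueError):
        gated_attention(x, g[:, :2], base)


# ---------------------------------------------------------------------------
# encoder transfer and segmentation network
# ---------------------------------------------------------------------------

def test_encoder_checkpoint_reproduces_features_bit_identically(rng,
                                                                tmp_path):
    from cspine.autodiff import load_checkpoint, save_checkpoint
    cfg = ViTConfig(in_chans=1, patch_size=8, d=32, depth=2, heads=4,
                    ref_grid=(2, 2, 2))
    enc = ViTEncoder(cfg, np.random.default_rng(0))
    x = rng.random((16, 16, 16)).astype(np.float32)
    with ad.no_grad():
        tokens, grid = enc.tokenize(x[None])
        ref = enc.forward(tokens, grid)[-1].data
    save_checkpoint(tmp_path / "enc.npz", enc.state_dict(), {})
    state, _ = load_checkpoint(tmp_path / "enc.npz")
    enc2 = ViTEncoder(cfg, np.random.default_rng(42))
    load_encoder_state(enc2, state)
    with ad.no_grad():
        out = enc2.forward(*enc2.tokenize(x[None]))[-1].data
    assert np.array_equal(out, ref)


def test_encoder_transfer_across_channel_counts(rng):
    """1-channel pretrained weights tiled into a 3-channel encoder give
    identical tokens on channel-replicated input."""
    cfg1 = ViTConfig(in_chans=1, patch_size=8, d=32, depth=2, heads=4,
                     ref_grid=(2, 2, 2))
    enc1 = ViTEncoder(cfg1, np.random.default_rng(0))
    cfg3 = ViTConfig(in_chans=3, patch_size=8, d=32, depth=2, heads=4,
                     ref_grid=(2, 2, 2))
    enc3 = ViTEncoder(cfg3, np.random.default_rng(1))
    load_encoder_state(enc3, enc1.state_dict())
    x = rng.random((16, 16, 16)).astype(np.float32)
    with ad.no_grad():
        ref = enc1.forward(*enc1.tokenize(x[None]))[-1].data
        rep = np.stack([x, x, x])
        out = enc3.forward(*enc3.tokenize(rep))[-1].data
    assert np.allclose(out, ref, atol=1e-5)


def test_seg_forward_contracts(rng):
    cfg = SegConfig(encoder=ViTConfig(in_chans=3, patch_size=8, d=32,
                                      depth=4, heads=4, ref_grid=(3, 3, 3)))
    net = SegNet(cfg, np.random.default_rng(2))
    x = rng.random((3, 24, 24, 24)).astype(np.float32)
    with ad.no_grad():
        logits = seg_forward(x, net)
        assert logits.shape == (8, 24, 24, 24)
        probs = logits.softmax(axis=0).data
        assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        again = seg_forward(x, net).data
    assert np.array_equal(again, logits.data)

    with pytest.raises(ValueError):
        seg_forward(rng.random((2, 24, 24, 24)), net)
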