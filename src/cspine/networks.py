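"""Shared transformer encoder, MAE decoder, and the gated-attention U-Net.

The encoder is a ViT over non-overlapping cubic patches: each patch is
flattened, linearly projected to dimension ``d``, and offset by a
learnable 3-D positional embedding that is trilinearly resized whenever
the token grid differs from the reference grid (transfer across
fields-of-view). The same encoder backs all three stages: masked
autoencoding (Stage 1), segmentation (Stage 2, skip taps from every
block), and ROI feature pooling (Stage 3).

The segmentation network is UNETR-style: token-grid features from the
four encoder blocks are brought to intermediate scales by stride-2
transposed convolutions and merged into an upsampling CNN decoder; each
skip passes through an additive attention gate (``q = θ_x*x + θ_g*g + b``,
``α = σ(ψᵀ ReLU(q))``, ``x̂ = α ⊙ x``) before concatenation. Residual
double-convolution blocks with group normalization refine each scale;
the full-resolution stage uses 1×1×1 convolutions to keep the memory
footprint of CPU training small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage

from .autodiff import (Conv3d, ConvTranspose3d, GroupNorm, LayerNorm,
                       Linear, Module, Parameter, Tensor, as_tensor, concat)

__all__ = [
    "msa",
    "resize_pos_embed",
    "GateParams",
    "gated_attention",
    "GatedAttention3d",
    "ViTConfig",
    "ViTEncoder",
    "MAEModel",
    "SegConfig",
    "SegNet",
    "seg_forward",
    "load_encoder_state",
]


# ---------------------------------------------------------------------------
# Multi-head self-attention (functional form)
# ---------------------------------------------------------------------------

def _stack_heads(w, d: int, heads: int):
    """Accept per-head projection lists [(d, d_h)] * H or a packed (d, d)."""
    if isinstance(w, (list, tuple)):
        w = np.concatenate([np.asarray(m, dtype=np.float32) for m in w],
                           axis=1)
    arr = w.data if isinstance(w, Tensor) else np.asarray(w, dtype=np.float32)
    if arr.shape != (d, d):
        raise ValueError(f"projection must pack to ({d},{d}), got {arr.shape}")
    return w if isinstance(w, Tensor) else Tensor(arr)


def msa(Z, w_q, w_k, w_v, w_o, heads: int = 1):
    """Canonical multi-head self-attention.

    ``Z`` is (N, d); per head h, ``softmax(Q_h K_hᵀ / √d_h) V_h`` with
    ``Q_h = Z W_h^Q`` etc.; head outputs are concatenated and projected
    by ``w_o``. Accepts numpy arrays (returns numpy) or Tensors (builds
    the autodiff graph).
    """
    numpy_in = not isinstance(Z, Tensor)
    Zt = as_tensor(Z)
    n, d = Zt.shape
    if d % heads:
        raise ValueError(f"model dim {d} not divisible by {heads} heads")
    dh = d // heads
    if numpy_in:
        # double-precision reference path for plain-array callers
        packs = []
        for w in (w_q, w_k, w_v):
            if isinstance(w, (list, tuple)):
                w = np.concatenate([np.asarray(m) for m in w], axis=1)
            packs.append(np.asarray(w, dtype=np.float64))
        wq64, wk64, wv64 = packs
        z64 = np.asarray(Z, dtype=np.float64)

        def split64(a):
            return a.reshape(n, heads, dh).transpose(1, 0, 2)

        q, k, v = split64(z64 @ wq64), split64(z64 @ wk64), split64(z64 @ wv64)
        s = q @ k.transpose(0, 2, 1) / np.sqrt(dh)
        s -= s.max(axis=-1, keepdims=True)
        a = np.exp(s)
        a /= a.sum(axis=-1, keepdims=True)
        out = (a @ v).transpose(1, 0, 2).reshape(n, d) @ np.asarray(
            w_o, dtype=np.float64)
        return out
    wq = _stack_heads(w_q, d, heads)
    wk = _stack_heads(w_k, d, heads)
    wv = _stack_heads(w_v, d, heads)
    wo = as_tensor(w_o)

    def split(t):  # (N, d) -> (H, N, d_h)
        return t.reshape(n, heads, dh).transpose((1, 0, 2))

    q = split(Zt @ wq)
    k = split(Zt @ wk)
    v = split(Zt @ wv)
    scores = (q @ k.transpose((0, 2, 1))) * (1.0 / np.sqrt(dh))
    attn = scores.softmax(axis=-1)
    return (attn @ v).transpose((1, 0, 2)).reshape(n, d) @ wo


# ---------------------------------------------------------------------------
# Positional-embedding resize
# ---------------------------------------------------------------------------

def resize_pos_embed(embed: np.ndarray, target_grid) -> np.ndarray:
    """Trilinearly resize a (gx, gy, gz, d) positional embedding to
    ``target_grid`` (align-corners convention); identity when the grids
    match."""
    embed = np.asarray(embed, dtype=np.float32)
    g1 = embed.shape[:3]
    g2 = tuple(int(v) for v in target_grid)
    if min(g1) < 1 or min(g2) < 1:
        raise ValueError("grids must be nonzero")
    if g1 == g2:
        return embed.copy()
    axes = [np.linspace(0.0, g1[a] - 1.0, g2[a]) for a in range(3)]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))
    out = np.empty(g2 + (embed.shape[3],), dtype=np.float32)
    for c in range(embed.shape[3]):
        out[..., c] = ndimage.map_coordinates(embed[..., c], coords, order=1,
                                              mode="nearest")
    return out


# ---------------------------------------------------------------------------
# Gated attention
# ---------------------------------------------------------------------------

@dataclass
class GateParams:
    """Parameters of one additive attention gate (arrays or Tensors).

    ``theta_x``: (inter, C_x); ``theta_g``: (inter, C_g); ``b``: (inter,);
    ``psi``: (inter,); ``psi_b``: scalar bias of the scoring projection.
    """

    theta_x: np.ndarray
    theta_g: np.ndarray
    b: np.ndarray
    psi: np.ndarray
    psi_b: float = 0.0


def gated_attention(x, g, params: GateParams):
    """Additive attention gate on co-registered feature maps.

    ``x`` (skip) and ``g`` (gating) have shape (C, *spatial) or are
    scalars/0-d per-voxel channels. Returns ``α ⊙ x`` with
    ``α = σ(ψᵀ ReLU(θ_x·x + θ_g·g + b))`` in (0, 1).
    """
    numpy_in = not isinstance(x, Tensor)
    xt, gt = as_tensor(x), as_tensor(g)
    if xt.ndim == 0:
        xt = xt.reshape(1, 1)
    if gt.ndim == 0:
        gt = gt.reshape(1, 1)
    if xt.shape[1:] != gt.shape[1:]:
        raise ValueError(f"spatial shapes differ: {xt.shape[1:]} vs "
                         f"{gt.shape[1:]}")
    tx = as_tensor(params.theta_x)
    tg = as_tensor(params.theta_g)
    b = as_tensor(params.b)
    psi = as_tensor(params.psi)
    inter = tx.shape[0]
    spatial = xt.shape[1:]
    nvox = int(np.prod(spatial)) if spatial else 1
    xf = xt.reshape(xt.shape[0], nvox)
    gf = gt.reshape(gt.shape[0], nvox)
    q = tx @ xf + tg @ gf + b.reshape(inter, 1)
    score = psi.reshape(1, inter) @ q.relu() + params.psi_b
    alpha = score.sigmoid()  # (1, nvox)
    out = (xf * alpha).reshape(xt.shape)
    return out.data if numpy_in else out


class GatedAttention3d(Module):
    """Gate module on (N, C, D, H, W) maps; 1×1×1 projections."""

    def __init__(self, c_x: int, c_g: int, rng, inter: int | None = None):
        inter = inter or max(c_x // 2, 1)
        self.theta_x = Conv3d(c_x, inter, 1, rng, padding=0)
        self.theta_g = Conv3d(c_g, inter, 1, rng, padding=0)
        self.psi = Conv3d(inter, 1, 1, rng, padding=0)

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        if x.shape[2:] != g.shape[2:]:
            raise ValueError("skip and gating features must share spatial "
                             f"shape, got {x.shape[2:]} vs {g.shape[2:]}")
        q = (self.theta_x(x) + self.theta_g(g)).relu()
        alpha = self.psi(q).sigmoid()
        return x * alpha


# ---------------------------------------------------------------------------
# ViT encoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViTConfig:
    in_chans: int = 1
    patch_size: int = 8
    d: int = 64
    depth: int = 4
    heads: int = 4
    mlp_ratio: int = 2
    ref_grid: tuple[int, int, int] = (4, 4, 4)

    def __post_init__(self):
        if self.d % self.heads:
            raise ValueError("d must be divisible by heads")


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, heads: int, rng):
        self.heads = heads
        self.w_q = Parameter(_ortho_init(rng, d))
        self.w_k = Parameter(_ortho_init(rng, d))
        self.w_v = Parameter(_ortho_init(rng, d))
        self.w_o = Parameter(_ortho_init(rng, d))

    def __call__(self, z: Tensor) -> Tensor:
        return msa(z, self.w_q, self.w_k, self.w_v, self.w_o,
                   heads=self.heads)


def _ortho_init(rng, d: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(0, 1, size=(d, d)))
    return (q / np.sqrt(d)).astype(np.float32)


class TransformerBlock(Module):
    def __init__(self, d: int, heads: int, mlp_ratio: int, rng):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, heads, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, d * mlp_ratio, rng)
        self.fc2 = Linear(d * mlp_ratio, d, rng)

    def __call__(self, z: Tensor) -> Tensor:
        z = z + self.attn(self.ln1(z))
        return z + self.fc2(self.fc1(self.ln2(z)).relu())


class ViTEncoder(Module):
    def __init__(self, config: ViTConfig, rng: np.random.Generator):
        self.config = config
        p, c, d = config.patch_size, config.in_chans, config.d
        self.patch_embed = Linear(p ** 3 * c, d, rng)
        self.pos_embed = Parameter(
            rng.normal(0, 0.02, size=config.ref_grid + (d,)).astype(np.float32))
        self.blocks = [TransformerBlock(d, config.heads, config.mlp_ratio, rng)
                       for _ in range(config.depth)]
        self.norm = LayerNorm(d)

    # -- tokenization ---------------------------------------------------
    def tokenize(self, channels: np.ndarray):
        """(C, X, Y, Z) HU-free normalized input -> (N, p³·C) patch
        vectors plus the token grid dims."""
        channels = np.asarray(channels, dtype=np.float32)
        if channels.ndim == 3:
            channels = channels[None]
        if channels.shape[0] != self.config.in_chans:
            raise ValueError(f"expected {self.config.in_chans} channels, "
                             f"got {channels.shape[0]}")
        p = self.config.patch_size
        c, X, Y, Z = channels.shape
        if X % p or Y % p or Z % p:
            raise ValueError(f"shape {(X, Y, Z)} not divisible by patch {p}")
        grid = (X // p, Y // p, Z // p)
        blocks = channels.reshape(c, grid[0], p, grid[1], p, grid[2], p)
        tokens = blocks.transpose(1, 3, 5, 0, 2, 4, 6).reshape(
            np.prod(grid), c * p ** 3)
        return tokens, grid

    def pos_for_grid(self, grid) -> np.ndarray:
        return resize_pos_embed(self.pos_embed.data, grid).reshape(
            -1, self.config.d)

    def embed(self, tokens, grid, visible_idx=None) -> Tensor:
        # At the reference grid the positional term is the learnable
        # parameter itself (gradient flows); at any other grid it is the
        # trilinearly resized copy, treated as data.
        if tuple(grid) == self.pos_embed.data.shape[:3]:
            pos = self.pos_embed.reshape(int(np.prod(grid)), self.config.d)
        else:
            pos = Tensor(self.pos_for_grid(grid))
        tok = as_tensor(tokens)
        if visible_idx is not None:
            vis = np.asarray(visible_idx)
            tok = tok[vis]
            pos = pos[vis]
        return self.patch_embed(tok) + pos

    def forward(self, tokens, grid, visible_idx=None) -> list[Tensor]:
        """Run all blocks; returns per-block outputs (last one normed)."""
        z = self.embed(tokens, grid, visible_idx)
        outs = []
        for blk in self.blocks:
            z = blk(z)
            outs.append(z)
        outs[-1] = self.norm(outs[-1])
        return outs


# ---------------------------------------------------------------------------
# Masked autoencoder
# ---------------------------------------------------------------------------

class MAEModel(Module):
    """Encoder on visible tokens + lightweight 2-block decoder with a
    single learned mask token and a linear per-patch reconstruction head."""

    def __init__(self, config: ViTConfig, rng: np.random.Generator,
                 decoder_depth: int = 2):
        self.encoder = ViTEncoder(config, rng)
        d = config.d
        self.mask_token = Parameter(
            rng.normal(0, 0.02, size=(d,)).astype(np.float32))
        self.dec_blocks = [TransformerBlock(d, config.heads,
                                            config.mlp_ratio, rng)
                           for _ in range(decoder_depth)]
        self.dec_norm = LayerNorm(d)
        self.head = Linear(d, config.patch_size ** 3 * config.in_chans, rng)

    def reconstruct(self, tokens: np.ndarray, grid,
                    visible_idx: np.ndarray) -> Tensor:
        """Encode visible tokens, fill masked slots with the mask token
        (+ positional embedding), decode, and predict all patches.
        Returns (N, p³·C) reconstructions."""
        n = tokens.shape[0]
        enc = self.encoder.forward(tokens, grid, visible_idx)[-1]
        pos = self.encoder.pos_for_grid(grid)
        d = self.encoder.config.d
        vis = np.asarray(visible_idx)
        mask = np.setdiff1d(np.arange(n), vis)
        # scatter encoder outputs and mask tokens back to full order
        order = np.argsort(np.concatenate([vis, mask]))
        mask_tok = self.mask_token.reshape(1, d) \
            * Tensor(np.ones((len(mask), 1), dtype=np.float32)) \
            + Tensor(pos[mask])
        full = concat([enc, mask_tok], axis=0)[order]
        z = full
        for blk in self.dec_blocks:
            z = blk(z)
        return self.head(self.dec_norm(z))


def load_encoder_state(encoder: ViTEncoder,
                       state: dict[str, np.ndarray]) -> None:
    """Load Stage-1 encoder weights into ``encoder``.

    Handles an input-channel mismatch (1-channel pretraining vs 3-channel
    segmentation input) by tiling the patch-embedding weights across the
    new channels and dividing by the channel count, so a channel-replicated
    input reproduces the pretrained activations. The positional embedding
    is trilinearly resized to the target reference grid if needed.
    """
    state = dict(state)
    tgt = encoder.named_parameters()
    w_key = "patch_embed.w"
    src_w = state[w_key]
    tgt_w = tgt[w_key].data
    if src_w.shape != tgt_w.shape:
        p3 = src_w.shape[0]
        reps = tgt_w.shape[0] // p3
        if tgt_w.shape[0] != reps * p3 or src_w.shape[1] != tgt_w.shape[1]:
            raise ValueError("incompatible patch-embedding shapes "
                             f"{src_w.shape} vs {tgt_w.shape}")
        state[w_key] = np.tile(src_w, (reps, 1)) / reps
    pe_key = "pos_embed"
    if state[pe_key].shape != tgt[pe_key].data.shape:
        state[pe_key] = resize_pos_embed(state[pe_key],
                                         tgt[pe_key].data.shape[:3])
    encoder.load_state_dict(state)


# ---------------------------------------------------------------------------
# Segmentation network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegConfig:
    encoder: ViTConfig = field(default_factory=lambda: ViTConfig(in_chans=3))
    base_channels: int = 8
    n_classes: int = 8

    def __post_init__(self):
        if self.encoder.in_chans != 3:
            raise ValueError("segmentation input must have 3 channels "
                             "(CT, bone-likelihood, edge map)")
        if self.encoder.patch_size != 8:
            raise ValueError("decoder performs three 2x upsamplings; "
                             "patch size must be 8")
        if self.encoder.depth != 4:
            raise ValueError("decoder taps skip features at blocks 1-4; "
                             "encoder depth must be 4")


def _norm_groups(c: int) -> int:
    for g in (4, 2, 1):
        if c % g == 0:
            return g
    return 1


class ResDoubleConv(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng):
        self.conv1 = Conv3d(c_in, c_out, k, rng)
        self.gn1 = GroupNorm(_norm_groups(c_out), c_out)
        self.conv2 = Conv3d(c_out, c_out, k, rng)
        self.gn2 = GroupNorm(_norm_groups(c_out), c_out)
        self.skip = Conv3d(c_in, c_out, 1, rng, padding=0) \
            if c_in != c_out else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.gn1(self.conv1(x)).relu()
        y = self.gn2(self.conv2(y))
        s = self.skip(x) if self.skip is not None else x
        return (y + s).relu()


class _DeconvChain(Module):
    """n stacked stride-2 transposed convolutions with GN+ReLU between."""

    def __init__(self, c_in: int, c_mid: int, c_out: int, n: int, rng):
        chans = [c_in] + [c_mid] * (n - 1) + [c_out]
        self.ups = [ConvTranspose3d(chans[i], chans[i + 1], rng)
                    for i in range(n)]
        self.norms = [GroupNorm(_norm_groups(chans[i + 1]), chans[i + 1])
                      for i in range(n - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for i, up in enumerate(self.ups):
            x = up(x)
            if i < len(self.norms):
                x = self.norms[i](x).relu()
        return x


class SegNet(Module):
    """UNETR-style segmentation network with gated-attention skips."""

    def __init__(self, config: SegConfig, rng: np.random.Generator):
        self.config = config
        self.encoder = ViTEncoder(config.encoder, rng)
        d = config.encoder.d
        c = config.base_channels
        self.bottleneck = Conv3d(d, 4 * c, 1, rng, padding=0)
        self.up3 = ConvTranspose3d(4 * c, 2 * c, rng)        # 1/8 -> 1/4
        self.skip3 = _DeconvChain(d, 2 * c, 2 * c, 1, rng)
        self.gate3 = GatedAttention3d(2 * c, 2 * c, rng)
        self.dec3 = ResDoubleConv(4 * c, 2 * c, 3, rng)
        self.up2 = ConvTranspose3d(2 * c, c, rng)            # 1/4 -> 1/2
        self.skip2 = _DeconvChain(d, 2 * c, c, 2, rng)
        self.gate2 = GatedAttention3d(c, c, rng)
        self.dec2 = ResDoubleConv(2 * c, c, 3, rng)
        self.up1 = ConvTranspose3d(c, c, rng)                # 1/2 -> full
        self.skip1 = _DeconvChain(d, 2 * c, c, 3, rng)
        self.gate1 = GatedAttention3d(c, c, rng)
        # full-resolution stem on the raw prior channels (first UNETR skip)
        self.stem = Conv3d(3, c, 3, rng)
        self.stem_gn = GroupNorm(_norm_groups(c), c)
        self.gate0 = GatedAttention3d(c, c, rng)
        self.dec1 = ResDoubleConv(3 * c, c, 1, rng)
        self.head = Conv3d(c, config.n_classes, 1, rng, padding=0)

    def _tap(self, z: Tensor, grid) -> Tensor:
        d = self.config.encoder.d
        return z.reshape(grid + (d,)).transpose((3, 0, 1, 2)).reshape(
            (1, d) + grid)

    def __call__(self, channels: np.ndarray) -> Tensor:
        """(3, X, Y, Z) prior stack -> (n_classes, X, Y, Z) logits."""
        channels = np.asarray(channels, dtype=np.float32)
        tokens, grid = self.encoder.tokenize(channels)
        z1, z2, z3, z4 = self.encoder.forward(tokens, grid)
        f4 = self.bottleneck(self._tap(z4, grid)).relu()
        u = self.up3(f4)
        s = self.gate3(self.skip3(self._tap(z3, grid)), u)
        x = self.dec3(concat([u, s], axis=1))
        u = self.up2(x)
        s = self.gate2(self.skip2(self._tap(z2, grid)), u)
        x = self.dec2(concat([u, s], axis=1))
        u = self.up1(x)
        s = self.gate1(self.skip1(self._tap(z1, grid)), u)
        s0 = self.stem_gn(self.stem(Tensor(channels[None]))).relu()
        s0 = self.gate0(s0, u)
        x = self.dec1(concat([u, s, s0], axis=1))
        logits = self.head(x)
        sp = logits.shape[2:]
        return logits.reshape((self.config.n_classes,) + sp)


def seg_forward(stack, net: SegNet) -> Tensor:
    """Per-voxel logits over the 8 classes for a
    :class:`~cspine.preprocess.PriorStack` (or a raw (3, X, Y, Z) array)."""
    channels = stack.channels() if hasattr(stack, "channels") else \
        np.asarray(stack, dtype=np.float32)
    if channels.shape[0] != 3:
        raise ValueError(f"expected 3 channels, got {channels.shape[0]}")
    return net(channels)
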