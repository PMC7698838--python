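"""Multi-branch 1-D CNN with residual-attention fusion and stage refinement.

Implemented directly on NumPy: the architecture is small and fixed, so the
forward and backward passes are written out explicitly (and verified against
finite differences in the test suite). Parameters live in a flat
``dict[str, ndarray]`` so the optimizer and checkpointing stay trivial.

Architecture, per 30-s epoch:

* one CNN branch per input channel (no parameter sharing): five blocks of
  unpadded 1-D convolution -> batch norm -> ReLU, then global average
  pooling to a feature vector ``v_i``;
* channel fusion: softmax attention over per-channel scores
  ``s_i = w_is . ReLU(W_iv v_i + W V + b)`` with the channel-mean feature
  added back as a residual floor (``V_fusion = v_avg + sum_i alpha_i v_i``);
* previous-stage refinement: the prior epoch's stage vector is affinely
  encoded to ``v_c`` and concatenated with ``V_fusion``, so the logits
  decompose additively as ``P = W_c v_c + W_f V_fusion + b``.

Ablation fusion modes (average / concat / attention-only / data fusion) and
a no-refinement head are supported for the comparison experiments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .stages import N_STAGES

FUSION_MODES = ("average", "concat", "attention_only", "residual_attention", "data")


# ----------------------------------------------------------------------------
# convolution arithmetic
# ----------------------------------------------------------------------------


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Temporal length of an unpadded ("VALID") 1-D convolution."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    return (length - kernel) // stride + 1


def block_output_lengths(input_len: int, blocks) -> list[int]:
    """Chain `conv_output_length` through a block list of (kernel, stride, filters)."""
    lengths = []
    L = input_len
    for k, s, _ in blocks:
        L = conv_output_length(L, k, s)
        lengths.append(L)
    return lengths


@dataclass(frozen=True)
class BackboneConfig:
    """Per-branch CNN hyperparameters: (kernel_length, stride, n_filters) blocks."""

    blocks: tuple = ((5, 3, 64), (5, 3, 64), (3, 2, 128), (3, 1, 128), (3, 1, 256))
    bn_momentum: float = 0.99
    bn_epsilon: float = 0.001

    @property
    def feature_dim(self) -> int:
        return self.blocks[-1][2]


@dataclass(frozen=True)
class ModelConfig:
    input_len: int
    n_channels: int
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fusion: str = "residual_attention"
    use_refinement: bool = True
    encoding_size: int | None = None  # None -> feature_dim
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion!r}; choose from {FUSION_MODES}")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        final = block_output_lengths(self.input_len, self.backbone.blocks)[-1]
        if final < 1:
            raise ValueError("backbone collapses the temporal axis below 1")

    @property
    def feature_dim(self) -> int:
        return self.backbone.feature_dim

    @property
    def enc_dim(self) -> int:
        return self.encoding_size or self.feature_dim

    @property
    def n_branches(self) -> int:
        return 1 if self.fusion == "data" else self.n_channels

    @property
    def fused_dim(self) -> int:
        if self.fusion == "concat":
            return self.feature_dim * self.n_channels
        return self.feature_dim

    @property
    def has_attention(self) -> bool:
        return self.fusion in ("attention_only", "residual_attention")


# ----------------------------------------------------------------------------
# functional pieces (shared by the model and usable standalone)
# ----------------------------------------------------------------------------


@dataclass
class AttentionParams:
    """Attention parameters; the per-channel maps are unshared."""

    W_iv: list  # C arrays of shape (F, F)
    W: np.ndarray  # (F, F*C), shared
    b: np.ndarray  # (F,)
    w_is: list  # C arrays of shape (F,)


def attention_weights(v: list[np.ndarray], params: AttentionParams) -> np.ndarray:
    """Softmax channel weights from per-channel scores (numerically stabilized).

    ``v`` holds C arrays of shape (B, F); returns alpha of shape (B, C).
    """
    V = np.concatenate(v, axis=1)
    scores = []
    for i, vi in enumerate(v):
        z = vi @ params.W_iv[i].T + V @ params.W.T + params.b
        h = np.maximum(z, 0.0)
        scores.append(h @ params.w_is[i])
    s = np.stack(scores, axis=1)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def fuse_residual(v: list[np.ndarray], alpha: np.ndarray) -> np.ndarray:
    """Channel-mean residual plus attention-weighted channel sum."""
    if alpha.shape[-1] != len(v):
        raise ValueError(f"alpha has {alpha.shape[-1]} weights for {len(v)} channels")
    stack = np.stack(v, axis=1)  # (B, C, F)
    v_avg = stack.mean(axis=1)
    return v_avg + np.einsum("bc,bcf->bf", alpha, stack)


def fuse_variant(
    v: list[np.ndarray], mode: str, alpha: np.ndarray | None = None
) -> np.ndarray:
    """Feature-level fusion ablations: average / concat / attention variants."""
    stack = np.stack(v, axis=1)
    if mode == "average":
        return stack.mean(axis=1)
    if mode == "concat":
        return np.concatenate(v, axis=1)
    if mode in ("attention_only", "residual_attention"):
        if alpha is None:
            raise ValueError(f"mode {mode!r} requires attention weights")
        weighted = np.einsum("bc,bcf->bf", alpha, stack)
        if mode == "attention_only":
            return weighted
        return stack.mean(axis=1) + weighted
    raise ValueError(f"unknown fusion mode {mode!r}")


def encode_previous_stage(stage_vec: np.ndarray, E: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine re-encoding of a length-5 stage vector into the feature space."""
    stage_vec = np.asarray(stage_vec, dtype=np.float64)
    squeeze = stage_vec.ndim == 1
    if squeeze:
        stage_vec = stage_vec[None, :]
    if stage_vec.shape[1] != N_STAGES:
        raise ValueError(f"stage vector must have length {N_STAGES}")
    if (stage_vec < -1e-9).any() or (stage_vec.sum(axis=1) > 1 + 1e-6).any():
        raise ValueError("stage vector entries must be >= 0 with sum <= 1")
    out = stage_vec @ E.T + b
    return out[0] if squeeze else out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def uniform_stage_vector() -> np.ndarray:
    """Previous-stage input for the first epoch of a recording."""
    return np.full(N_STAGES, 1.0 / N_STAGES)


# ----------------------------------------------------------------------------
# im2col helpers
# ----------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, s: int) -> np.ndarray:
    """(B, L, Cin) -> (B, T, k*Cin) windows for a strided valid convolution."""
    B, L, Cin = x.shape
    T = conv_output_length(L, k, s)
    idx = np.arange(T)[:, None] * s + np.arange(k)[None, :]
    cols = x[:, idx, :]  # (B, T, k, Cin)
    return cols.reshape(B, T, k * Cin)


def _col2im(dcols: np.ndarray, L: int, k: int, s: int, Cin: int) -> np.ndarray:
    """Scatter-add window gradients back onto the input signal."""
    B, T, _ = dcols.shape
    dcols = dcols.reshape(B, T, k, Cin)
    dx = np.zeros((B, L, Cin))
    for j in range(k):
        dx[:, j : j + T * s : s, :] += dcols[:, :, j, :]
    return dx


# ----------------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------------


class SleepStageModel:
    """Trainable multi-branch classifier; parameters in ``self.params``.

    ``self.state`` carries the batch-norm running statistics (non-trainable).
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- construction -------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        F = cfg.feature_dim
        C = cfg.n_channels
        for i in range(cfg.n_branches):
            c_in = C if cfg.fusion == "data" else 1
            for j, (k, s, f) in enumerate(cfg.backbone.blocks):
                fan_in = k * c_in
                self.params[f"branch{i}.block{j}.W"] = (
                    rng.standard_normal((fan_in, f)) * np.sqrt(2.0 / fan_in)
                )
                self.params[f"branch{i}.block{j}.gamma"] = np.ones(f)
                self.params[f"branch{i}.block{j}.beta"] = np.zeros(f)
                self.state[f"branch{i}.block{j}.running_mean"] = np.zeros(f)
                self.state[f"branch{i}.block{j}.running_var"] = np.ones(f)
                c_in = f
        if cfg.has_attention:
            for i in range(C):
                self.params[f"att.Wiv{i}"] = rng.standard_normal((F, F)) * np.sqrt(1.0 / F)
                self.params[f"att.wis{i}"] = rng.standard_normal(F) * np.sqrt(1.0 / F)
            self.params["att.W"] = rng.standard_normal((F, F * C)) * np.sqrt(1.0 / (F * C))
            self.params["att.b"] = np.zeros(F)
        if cfg.use_refinement:
            E = cfg.enc_dim
            self.params["enc.E"] = rng.standard_normal((E, N_STAGES)) * np.sqrt(1.0 / N_STAGES)
            self.params["enc.b"] = np.zeros(E)
            self.params["cls.Wc"] = rng.standard_normal((N_STAGES, E)) * np.sqrt(1.0 / E)
        fd = cfg.fused_dim
        self.params["cls.Wf"] = rng.standard_normal((N_STAGES, fd)) * np.sqrt(1.0 / fd)
        self.params["cls.b"] = np.zeros(N_STAGES)

    def attention_params(self) -> AttentionParams:
        C = self.config.n_channels
        return AttentionParams(
            W_iv=[self.params[f"att.Wiv{i}"] for i in range(C)],
            W=self.params["att.W"],
            b=self.params["att.b"],
            w_is=[self.params[f"att.wis{i}"] for i in range(C)],
        )

    # -- forward ------------------------------------------------------------

    def _branch_forward(self, x: np.ndarray, branch: int, train: bool, cache: dict | None):
        """x: (B, L, c_in) -> pooled feature (B, F)."""
        cfg = self.config
        mom, eps = cfg.backbone.bn_momentum, cfg.backbone.bn_epsilon
        h = x
        for j, (k, s, f) in enumerate(cfg.backbone.blocks):
            key = f"branch{branch}.block{j}"
            cols = _im2col(h, k, s)
            z = cols @ self.params[f"{key}.W"]
            if train:
                mean = z.mean(axis=(0, 1))
                var = z.var(axis=(0, 1))
                self.state[f"{key}.running_mean"] = (
                    mom * self.state[f"{key}.running_mean"] + (1 - mom) * mean
                )
                self.state[f"{key}.running_var"] = (
                    mom * self.state[f"{key}.running_var"] + (1 - mom) * var
                )
            else:
                mean = self.state[f"{key}.running_mean"]
                var = self.state[f"{key}.running_var"]
            inv_sd = 1.0 / np.sqrt(var + eps)
            xhat = (z - mean) * inv_sd
            bn = self.params[f"{key}.gamma"] * xhat + self.params[f"{key}.beta"]
            out = np.maximum(bn, 0.0)
            if cache is not None:
                cache[f"{key}.in_shape"] = h.shape
                cache[f"{key}.cols"] = cols
                cache[f"{key}.xhat"] = xhat
                cache[f"{key}.inv_sd"] = inv_sd
                cache[f"{key}.relu_mask"] = bn > 0
            h = out
        v = h.mean(axis=1)
        if cache is not None:
            cache[f"branch{branch}.T"] = h.shape[1]
        return v

    def extract_features(self, epoch: np.ndarray, branch_id: int = 0) -> np.ndarray:
        """Per-branch feature vector for single-channel input (inference mode)."""
        epoch = np.asarray(epoch, dtype=np.float64)
        squeeze = epoch.ndim == 1
        if squeeze:
            epoch = epoch[None, :]
        if epoch.ndim == 2:
            epoch = epoch[:, :, None]
        expected = self.config.input_len
        if epoch.shape[1] != expected:
            raise ValueError(f"expected input length {expected}, got {epoch.shape[1]}")
        v = self._branch_forward(epoch, branch_id, train=False, cache=None)
        return v[0] if squeeze else v

    def _fuse_forward(self, x: np.ndarray, train: bool, cache: dict | None):
        """Branch features + fusion; returns (fused, v_list, alpha)."""
        cfg = self.config
        if cfg.fusion == "data":
            fused = self._branch_forward(x, 0, train, cache)
            return fused, [fused], None
        v = [
            self._branch_forward(x[:, :, i : i + 1], i, train, cache)
            for i in range(cfg.n_channels)
        ]
        alpha = None
        if cfg.has_attention:
            ap = self.attention_params()
            V = np.concatenate(v, axis=1)
            z_list, h_list, scores = [], [], []
            for i, vi in enumerate(v):
                z = vi @ ap.W_iv[i].T + V @ ap.W.T + ap.b
                h = np.maximum(z, 0.0)
                z_list.append(z)
                h_list.append(h)
                scores.append(h @ ap.w_is[i])
            s = np.stack(scores, axis=1)
            alpha = softmax(s, axis=1)
            if cache is not None:
                cache["att.V"] = V
                cache["att.z"] = z_list
                cache["att.h"] = h_list
                cache["att.alpha"] = alpha
        fused = fuse_variant(v, cfg.fusion, alpha)
        return fused, v, alpha

    def forward(
        self,
        x: np.ndarray,
        prev_stage: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        cache_out: dict | None = None,
    ) -> np.ndarray:
        """Probability vectors (B, 5) for epochs x (B, L, C) given previous stages."""
        cfg = self.config
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != cfg.input_len:
            raise ValueError(f"expected input length {cfg.input_len}, got {x.shape[1]}")
        if x.shape[2] != cfg.n_channels:
            raise ValueError(f"expected {cfg.n_channels} channels, got {x.shape[2]}")
        cache = cache_out if cache_out is not None else None
        fused, v, alpha = self._fuse_forward(x, train, cache)
        B = x.shape[0]
        if cfg.use_refinement:
            prev = np.asarray(prev_stage, dtype=np.float64)
            if prev.ndim == 1:
                prev = np.broadcast_to(prev, (B, N_STAGES)).copy()
            v_c = prev @ self.params["enc.E"].T + self.params["enc.b"]
        else:
            prev = None
            v_c = None
        # dropout on the concatenated [v_c, fused] vector, training only
        if train and cfg.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            keep = 1.0 - cfg.dropout
            if v_c is not None:
                mask_c = (rng.random(v_c.shape) < keep) / keep
                mask_f = (rng.random(fused.shape) < keep) / keep
            else:
                mask_c = None
                mask_f = (rng.random(fused.shape) < keep) / keep
        else:
            mask_c = mask_f = None
        fused_d = fused * mask_f if mask_f is not None else fused
        logits = fused_d @ self.params["cls.Wf"].T + self.params["cls.b"]
        if v_c is not None:
            v_c_d = v_c * mask_c if mask_c is not None else v_c
            logits = logits + v_c_d @ self.params["cls.Wc"].T
        else:
            v_c_d = None
        probs = softmax(logits, axis=1)
        if cache is not None:
            cache.update(
                x=x, v=v, fused=fused, fused_d=fused_d, v_c=v_c, v_c_d=v_c_d,
                prev=prev, mask_c=mask_c, mask_f=mask_f, probs=probs, train=train,
            )
        return probs

    def classify(
        self, v_c: np.ndarray | None, fused: np.ndarray, train_mode: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Head only: dropout (train) -> additive logits -> softmax."""
        cfg = self.config
        squeeze = fused.ndim == 1
        fused = np.atleast_2d(fused)
        if train_mode and cfg.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            keep = 1.0 - cfg.dropout
            fused = fused * (rng.random(fused.shape) < keep) / keep
        logits = fused @ self.params["cls.Wf"].T + self.params["cls.b"]
        if v_c is not None and cfg.use_refinement:
            v_c = np.atleast_2d(v_c)
            if train_mode and cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                v_c = v_c * (rng.random(v_c.shape) < keep) / keep
            logits = logits + v_c @ self.params["cls.Wc"].T
        probs = softmax(logits, axis=1)
        return probs[0] if squeeze else probs

    # -- backward -----------------------------------------------------------

    def backward(self, cache: dict, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Mean cross-entropy gradients for a cached training forward pass."""
        cfg = self.config
        probs = cache["probs"]
        B = probs.shape[0]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = (probs - y_onehot) / B
        grads["cls.Wf"] += dlogits.T @ cache["fused_d"]
        grads["cls.b"] += dlogits.sum(axis=0)
        dfused = dlogits @ self.params["cls.Wf"]
        if cache["mask_f"] is not None:
            dfused = dfused * cache["mask_f"]
        if cfg.use_refinement:
            grads["cls.Wc"] += dlogits.T @ cache["v_c_d"]
            dv_c = dlogits @ self.params["cls.Wc"]
            if cache["mask_c"] is not None:
                dv_c = dv_c * cache["mask_c"]
            grads["enc.E"] += dv_c.T @ cache["prev"]
            grads["enc.b"] += dv_c.sum(axis=0)

        if cfg.fusion == "data":
            self._branch_backward(dfused, 0, cache, grads)
            return grads

        v = cache["v"]
        C = cfg.n_channels
        F = cfg.feature_dim
        dv = [np.zeros_like(vi) for vi in v]
        dalpha = None
        if cfg.fusion == "average":
            for i in range(C):
                dv[i] += dfused / C
        elif cfg.fusion == "concat":
            for i in range(C):
                dv[i] += dfused[:, i * F : (i + 1) * F]
        else:
            alpha = cache["att.alpha"]
            dalpha = np.stack([(dfused * vi).sum(axis=1) for vi in v], axis=1)
            for i in range(C):
                dv[i] += alpha[:, i : i + 1] * dfused
                if cfg.fusion == "residual_attention":
                    dv[i] += dfused / C
        if dalpha is not None:
            alpha = cache["att.alpha"]
            ds = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
            V = cache["att.V"]
            dV = np.zeros_like(V)
            for i in range(C):
                h = cache["att.h"][i]
                z = cache["att.z"][i]
                dsi = ds[:, i]
                grads[f"att.wis{i}"] += h.T @ dsi
                dh = dsi[:, None] * self.params[f"att.wis{i}"][None, :]
                dz = dh * (z > 0)
                grads[f"att.Wiv{i}"] += dz.T @ v[i]
                grads["att.W"] += dz.T @ V
                grads["att.b"] += dz.sum(axis=0)
                dv[i] += dz @ self.params[f"att.Wiv{i}"]
                dV += dz @ self.params["att.W"]
            for i in range(C):
                dv[i] += dV[:, i * F : (i + 1) * F]

        for i in range(C):
            self._branch_backward(dv[i], i, cache, grads)
        return grads

    def _branch_backward(self, dv: np.ndarray, branch: int, cache: dict, grads: dict) -> None:
        cfg = self.config
        eps = cfg.backbone.bn_epsilon
        T = cache[f"branch{branch}.T"]
        dh = np.repeat(dv[:, None, :], T, axis=1) / T
        for j in reversed(range(len(cfg.backbone.blocks))):
            key = f"branch{branch}.block{j}"
            dbn = dh * cache[f"{key}.relu_mask"]
            xhat = cache[f"{key}.xhat"]
            inv_sd = cache[f"{key}.inv_sd"]
            gamma = self.params[f"{key}.gamma"]
            grads[f"{key}.gamma"] += (dbn * xhat).sum(axis=(0, 1))
            grads[f"{key}.beta"] += dbn.sum(axis=(0, 1))
            dxhat = dbn * gamma
            N = dbn.shape[0] * dbn.shape[1]
            dz = (inv_sd / N) * (
                N * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
            cols = cache[f"{key}.cols"]
            W = self.params[f"{key}.W"]
            kc, f = W.shape
            grads[f"{key}.W"] += cols.reshape(-1, kc).T @ dz.reshape(-1, f)
            dcols = dz @ W.T
            k, s, _ = cfg.backbone.blocks[j]
            in_shape = cache[f"{key}.in_shape"]
            dh = _col2im(dcols, in_shape[1], k, s, in_shape[2])
        # gradient w.r.t. the input signal is discarded

    # -- checkpointing ------------------------------------------------------

    def snapshot(self) -> dict:
        return {
            "params": copy.deepcopy(self.params),
            "state": copy.deepcopy(self.state),
        }

    def restore(self, snap: dict) -> None:
        self.params = copy.deepcopy(snap["params"])
        self.state = copy.deepcopy(snap["state"])

    def save(self, path) -> None:
        arrays = {f"p::{k}": v for k, v in self.params.items()}
        arrays.update({f"s::{k}": v for k, v in self.state.items()})
        np.savez(path, **arrays)

    def load(self, path) -> None:
        with np.load(path) as data:
            for key in data.files:
                kind, name = key.split("::", 1)
                target = self.params if kind == "p" else self.state
                if name not in target:
                    raise KeyError(f"checkpoint key {name!r} not in model")
                target[name] = data[key]
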