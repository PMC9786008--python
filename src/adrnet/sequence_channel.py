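"""Self-attention channel over the 256-token substructure sequence.

Pipeline (single encoder block, no positional encoding):

1. token embedding (16-symbol hexadecimal vocabulary) followed by layer
   normalization across the embedding dimension per token position;
2. H-head scaled dot-product self-attention, heads concatenated and
   projected by W_o, residual connection to the block input, second layer
   normalization;
3. feedforward compressor: flatten to 256*dim', linear to dim_ff, batch
   normalization, linear to dim, LeakyReLU (activation outermost).

Dropout (rate 0.5 by default, matching the tuned setting) is applied to the
attention weights and to the feedforward hidden layer, in training mode
only. Without positional encodings the attention block is permutation
equivariant in the token positions; token identity is carried by the token
values alone.

Functions here accept any sequence length L (the model always uses L=256);
short inputs keep oracle tests cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Tensor, concat
from .errors import ConfigurationError, FeaturizationError
from .featurize import SEQUENCE_LENGTH, SubstructureSequence

VOCAB_SIZE = 16

DEFAULT_DIM_PRIME = 64
DEFAULT_DIM_FF = 1024
DEFAULT_OUT_DIM = 300
DEFAULT_HEADS = 2


@dataclass
class EncoderParams:
    """All learnable tensors of the sequence channel.

    The per-head projections are stacked: ``Wq``, ``Wk``, ``Wv`` have shape
    (H, dim', d_v) with d_v = dim'/H enforced exactly. ``bn_*`` are the
    batch-norm affine parameters and running statistics of the feedforward
    hidden layer.
    """

    dim_prime: int
    n_heads: int
    dim_ff: int
    out_dim: int
    seq_len: int
    dropout_rate: float
    eps: float
    embedding: Tensor  # (16, dim')
    ln1_gamma: Tensor  # (dim',)
    ln1_beta: Tensor
    Wq: Tensor  # (H, dim', d_v)
    Wk: Tensor
    Wv: Tensor
    Wo: Tensor  # (H * d_v, dim')
    ln2_gamma: Tensor
    ln2_beta: Tensor
    W_layer1: Tensor  # (seq_len * dim', dim_ff)
    bn_gamma: Tensor  # (dim_ff,)
    bn_beta: Tensor
    W_layer2: Tensor  # (dim_ff, out_dim)
    bn_running_mean: np.ndarray = None
    bn_running_var: np.ndarray = None
    bn_momentum: float = 0.1

    def __post_init__(self):
        if self.dim_prime % self.n_heads != 0:
            raise ConfigurationError(
                f"d_v = dim'/H must be an integer; got dim'={self.dim_prime}, "
                f"H={self.n_heads}"
            )
        if self.eps <= 0:
            raise ConfigurationError("eps must be positive")
        d_v = self.d_v
        expected = {
            "embedding": (VOCAB_SIZE, self.dim_prime),
            "ln1_gamma": (self.dim_prime,),
            "ln1_beta": (self.dim_prime,),
            "Wq": (self.n_heads, self.dim_prime, d_v),
            "Wk": (self.n_heads, self.dim_prime, d_v),
            "Wv": (self.n_heads, self.dim_prime, d_v),
            "Wo": (self.n_heads * d_v, self.dim_prime),
            "ln2_gamma": (self.dim_prime,),
            "ln2_beta": (self.dim_prime,),
            "W_layer1": (self.seq_len * self.dim_prime, self.dim_ff),
            "bn_gamma": (self.dim_ff,),
            "bn_beta": (self.dim_ff,),
            "W_layer2": (self.dim_ff, self.out_dim),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ConfigurationError(
                    f"{name} has shape {got}, expected {shape}"
                )
        if self.bn_running_mean is None:
            self.bn_running_mean = np.zeros(self.dim_ff, dtype=self.embedding.dtype)
        if self.bn_running_var is None:
            self.bn_running_var = np.ones(self.dim_ff, dtype=self.embedding.dtype)

    @property
    def d_v(self) -> int:
        return self.dim_prime // self.n_heads

    def tensors(self) -> list[Tensor]:
        return [
            self.embedding,
            self.ln1_gamma,
            self.ln1_beta,
            self.Wq,
            self.Wk,
            self.Wv,
            self.Wo,
            self.ln2_gamma,
            self.ln2_beta,
            self.W_layer1,
            self.bn_gamma,
            self.bn_beta,
            self.W_layer2,
        ]

    def copy(self) -> "EncoderParams":
        kwargs = {
            name: Tensor(getattr(self, name).data.copy(), requires_grad=True)
            for name in (
                "embedding",
                "ln1_gamma",
                "ln1_beta",
                "Wq",
                "Wk",
                "Wv",
                "Wo",
                "ln2_gamma",
                "ln2_beta",
                "W_layer1",
                "bn_gamma",
                "bn_beta",
                "W_layer2",
            )
        }
        return replace(
            self,
            bn_running_mean=self.bn_running_mean.copy(),
            bn_running_var=self.bn_running_var.copy(),
            **kwargs,
        )


def init_encoder_params(
    dim_prime: int = DEFAULT_DIM_PRIME,
    n_heads: int = DEFAULT_HEADS,
    dim_ff: int = DEFAULT_DIM_FF,
    out_dim: int = DEFAULT_OUT_DIM,
    seq_len: int = SEQUENCE_LENGTH,
    dropout_rate: float = 0.5,
    eps: float = 1e-5,
    seed: int = 0,
    dtype=np.float32,
) -> EncoderParams:
    """Seeded Glorot-style initialization of the sequence channel."""
    if dim_prime % n_heads != 0:
        raise ConfigurationError(
            f"d_v = dim'/H must be an integer; got dim'={dim_prime}, H={n_heads}"
        )
    rng = np.random.default_rng(seed)
    d_v = dim_prime // n_heads

    def glorot(*shape):
        fan_in, fan_out = shape[-2], shape[-1]
        std = np.sqrt(2.0 / (fan_in + fan_out))
        return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)

    def ones(n):
        return Tensor(np.ones(n, dtype=dtype), requires_grad=True)

    def zeros(n):
        return Tensor(np.zeros(n, dtype=dtype), requires_grad=True)

    return EncoderParams(
        dim_prime=dim_prime,
        n_heads=n_heads,
        dim_ff=dim_ff,
        out_dim=out_dim,
        seq_len=seq_len,
        dropout_rate=dropout_rate,
        eps=eps,
        embedding=Tensor(
            rng.normal(0.0, 1.0, size=(VOCAB_SIZE, dim_prime)).astype(dtype),
            requires_grad=True,
        ),
        ln1_gamma=ones(dim_prime),
        ln1_beta=zeros(dim_prime),
        Wq=glorot(n_heads, dim_prime, d_v),
        Wk=glorot(n_heads, dim_prime, d_v),
        Wv=glorot(n_heads, dim_prime, d_v),
        Wo=glorot(n_heads * d_v, dim_prime),
        ln2_gamma=ones(dim_prime),
        ln2_beta=zeros(dim_prime),
        W_layer1=glorot(seq_len * dim_prime, dim_ff),
        bn_gamma=ones(dim_ff),
        bn_beta=zeros(dim_ff),
        W_layer2=glorot(dim_ff, out_dim),
    )


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    """Normalize across the last (embedding) dimension, then affine."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xn = xc * ((var + eps) ** -0.5)
    return xn * gamma + beta


def _token_array(seq, params: EncoderParams) -> np.ndarray:
    """Accept a SubstructureSequence or an int token array; validate range."""
    if isinstance(seq, SubstructureSequence):
        ids = seq.token_ids()
    else:
        ids = np.asarray(seq, dtype=np.int64)
    if ids.ndim != 1:
        raise ConfigurationError("token input must be one-dimensional")
    if ids.size == 0:
        raise FeaturizationError("empty token sequence")
    if ids.min() < 0 or ids.max() >= VOCAB_SIZE:
        raise FeaturizationError(
            "token outside the 16-symbol hexadecimal alphabet"
        )
    return ids


def embed_and_norm(seq, params: EncoderParams) -> Tensor:
    """Token embedding followed by per-position layer normalization.

    Returns an (L, dim') tensor; L = 256 for real substructure sequences.
    """
    ids = _token_array(seq, params)
    E = params.embedding.take_rows(ids)
    return _layer_norm(E, params.ln1_gamma, params.ln1_beta, params.eps)


def embed_and_norm_batch(token_ids: np.ndarray, params: EncoderParams) -> Tensor:
    """Batched variant: (B, L) int tokens -> (B, L, dim')."""
    ids = np.asarray(token_ids, dtype=np.int64)
    B, L = ids.shape
    E = params.embedding.take_rows(ids.reshape(-1)).reshape(B, L, params.dim_prime)
    return _layer_norm(E, params.ln1_gamma, params.ln1_beta, params.eps)


def _head_projection(params: EncoderParams, which: str, head: int) -> Tensor:
    tensor = getattr(params, which)
    if not 0 <= head < params.n_heads:
        raise ConfigurationError(
            f"head index {head} outside [0, {params.n_heads})"
        )
    return tensor.take_rows(np.array([head])).reshape(params.dim_prime, params.d_v)


def attention_weights(E: Tensor, params: EncoderParams, head: int) -> Tensor:
    """Row-stochastic (L, L) attention matrix of one head."""
    Wq = _head_projection(params, "Wq", head)
    Wk = _head_projection(params, "Wk", head)
    Q = E @ Wq
    K = E @ Wk
    scores = (Q @ K.swap_last_axes()) * (1.0 / np.sqrt(params.d_v))
    return scores.softmax()


def self_attention(E: Tensor, params: EncoderParams, head: int = 0) -> Tensor:
    """Scaled dot-product self-attention of one head: (L, dim') -> (L, d_v).

    Output row s is the attention-weighted sum over positions j of the
    value vectors V_j.
    """
    E = E if isinstance(E, Tensor) else Tensor(E)
    if E.shape[-1] != params.dim_prime:
        raise ConfigurationError(
            f"input width {E.shape[-1]} does not match dim'={params.dim_prime}"
        )
    Wv = _head_projection(params, "Wv", head)
    alpha = attention_weights(E, params, head)
    return alpha @ (E @ Wv)


def multi_head_encode(
    E: Tensor,
    params: EncoderParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Multi-head attention block with residual and second layer norm.

    Heads run on the same input, are concatenated along the feature axis,
    projected by W_o, added element-wise to the block input, and layer
    normalized. Accepts (L, dim') or batched (B, L, dim') input.
    """
    E = E if isinstance(E, Tensor) else Tensor(E)
    scale = 1.0 / np.sqrt(params.d_v)
    heads = []
    for h in range(params.n_heads):
        Wq = _head_projection(params, "Wq", h)
        Wk = _head_projection(params, "Wk", h)
        Wv = _head_projection(params, "Wv", h)
        Q = E @ Wq
        K = E @ Wk
        alpha = ((Q @ K.swap_last_axes()) * scale).softmax()
        if training and rng is not None:
            alpha = alpha.dropout(params.dropout_rate, rng)
        heads.append(alpha @ (E @ Wv))
    O = concat(heads, axis=-1) @ params.Wo
    return _layer_norm(O + E, params.ln2_gamma, params.ln2_beta, params.eps)


def _batch_norm(
    x: Tensor,
    params: EncoderParams,
    training: bool,
) -> Tensor:
    """Batch normalization over the batch axis of a (B, dim_ff) tensor.

    Training mode uses batch statistics and updates the running estimates;
    evaluation mode normalizes with the stored running statistics, making
    single-sample inference well defined.
    """
    if training and x.shape[0] >= 2:  # single samples fall back to running stats
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=0, keepdims=True)
        m = params.bn_momentum
        n = x.shape[0]
        params.bn_running_mean = (1 - m) * params.bn_running_mean + m * mu.data[0]
        unbiased = var.data[0] * n / max(n - 1, 1)
        params.bn_running_var = (1 - m) * params.bn_running_var + m * unbiased
        xn = xc * ((var + params.eps) ** -0.5)
    else:
        xn = (x - Tensor(params.bn_running_mean)) * Tensor(
            1.0 / np.sqrt(params.bn_running_var + params.eps)
        )
    return xn * params.bn_gamma + params.bn_beta


def feedforward_project(
    O: Tensor,
    params: EncoderParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Compress encoder output to the channel feature X^f of width ``dim``.

    Literal nesting: LeakyReLU(BN(Flatten(O) W_layer1) W_layer2), i.e. the
    batch norm sits between the linear layers and the activation is
    outermost. Accepts (L, dim') for one molecule or (B, L, dim') batched;
    returns (dim,) or (B, dim) accordingly.
    """
    O = O if isinstance(O, Tensor) else Tensor(O)
    single = O.ndim == 2
    if single:
        O = O.reshape(1, *O.shape)
    B = O.shape[0]
    flat = O.reshape(B, params.seq_len * params.dim_prime)
    hidden = _batch_norm(flat @ params.W_layer1, params, training)
    if training and rng is not None:
        hidden = hidden.dropout(params.dropout_rate, rng)
    out = (hidden @ params.W_layer2).leaky_relu()
    return out.reshape(params.out_dim) if single else out


def sequence_encode_batch(
    token_ids: np.ndarray,
    params: EncoderParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Full sequence channel on a (B, 256) token batch -> (B, dim)."""
    E = embed_and_norm_batch(token_ids, params)
    O = multi_head_encode(E, params, training=training, rng=rng)
    return feedforward_project(O, params, training=training, rng=rng)
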