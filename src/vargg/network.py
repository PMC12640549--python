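"""The VARGG network and its training loop.

The model couples three pieces, trained jointly full-batch with Adam:

* bias-free multi-head self-attention stages over spots (8 heads on the
  input matrix, 4 heads after the first denoising-encoder layer, 8 heads in
  front of the decoder stack);
* a denoising linear autoencoder: affine stack X (N x M) -> Z_E (N x G),
  Gaussian corruption H0 = Z_E + eps with eps ~ N(0, sigma^2) during
  training, and a decoder reconstructing X from Z + Z_E;
* a variational graph encoder built from gated residual graph convolutions
  over the symmetrized spatial kNN adjacency, producing per-spot (mu,
  log sigma^2); the latent Z is obtained by reparameterization and decoded
  to edge probabilities via the inner product sigmoid(z_i . z_j).

The loss is mw * MSE + kw * KL + aw * adjacency-BCE. Two reparameterization
modes are available: ``standard`` (mu + exp(logvar/2) * theta, the form
consistent with the Gaussian KL) and ``paper_literal``
(mu + logvar * theta). The clustering input is mu, so domain calls are
deterministic at inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Parameter, Tensor
from .errors import ConsistencyError, ParameterError, VarggError
from .graph import BinaryAdjacency

__all__ = [
    "VarggConfig",
    "LossBreakdown",
    "FitResult",
    "MultiHeadAttention",
    "Linear",
    "ResGatedGraphLayer",
    "VarggModel",
    "gated_graph_layer",
    "multi_head_attention",
    "corrupt",
    "reparameterize",
    "decode_adjacency",
    "compute_loss",
    "fit",
]

_CLIP_LO, _CLIP_HI = 1e-7, 1.0 - 1e-7


@dataclass
class VarggConfig:
    """Architecture, loss, and training hyperparameters.

    ``latent_dim`` must equal the last denoising-encoder width (the decoder
    consumes the elementwise sum Z + Z_E), and every attention stage's
    embedding dimension must be divisible by its head count.
    """

    input_dim: int = 200
    attention_heads: tuple[int, int, int] = (8, 4, 8)
    dae_hidden_dims: tuple[int, ...] = (128, 32)
    graph_hidden_dims: tuple[int, ...] = (64,)
    latent_dim: int = 32
    noise_sigma: float = 0.1
    loss_weights: tuple[float, float, float] = (1.0, 0.01, 0.1)  # mw, kw, aw
    reparam_mode: str = "standard"
    learning_rate: float = 1e-3
    epochs: int = 500
    seed: int = 0
    use_attention: bool = True
    dtype: str = "float32"
    bce_dense_limit: int = 2000

    def validate(self) -> None:
        if self.reparam_mode not in ("standard", "paper_literal"):
            raise ParameterError(f"unknown reparam_mode {self.reparam_mode!r}")
        if self.latent_dim != self.dae_hidden_dims[-1]:
            raise ParameterError(
                "latent_dim must equal the final denoising-encoder width "
                f"({self.latent_dim} != {self.dae_hidden_dims[-1]}): the decoder "
                "sums Z and Z_E elementwise")
        if self.use_attention:
            stages = [("input", self.input_dim, self.attention_heads[0]),
                      ("post_encoder1", self.dae_hidden_dims[0], self.attention_heads[1]),
                      ("decoder", self.latent_dim, self.attention_heads[2])]
            for name, dim, heads in stages:
                if dim % heads != 0:
                    raise ParameterError(
                        f"{name} attention: embedding dim {dim} not divisible "
                        f"by {heads} heads")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class LossBreakdown:
    mse: float
    kl: float
    adj_bce: float
    total: float

    @classmethod
    def combine(cls, mse: float, kl: float, adj_bce: float,
                weights: tuple[float, float, float]) -> "LossBreakdown":
        mw, kw, aw = weights
        return cls(mse, kl, adj_bce, mw * mse + kw * kl + aw * adj_bce)


@dataclass
class FitResult:
    latent: np.ndarray          # (N, R) posterior means at convergence
    reconstruction: np.ndarray  # (N, M)
    adjacency_probs: np.ndarray  # probability per (symmetrized) edge
    loss_trace: list
    config: VarggConfig
    seed: int

    def to_dir(self, path, spot_ids=None) -> None:
        import pandas as pd
        import yaml
        from pathlib import Path
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        ids = np.asarray(spot_ids, dtype=str) if spot_ids is not None \
            else np.array([f"spot_{i}" for i in range(self.latent.shape[0])])
        lat = pd.DataFrame(self.latent, index=ids)
        lat.index.name = "spot_id"
        lat.to_csv(root / "latent.tsv", sep="\t")
        pd.DataFrame([asdict(lb) for lb in self.loss_trace]).assign(
            epoch=np.arange(len(self.loss_trace))).to_csv(
            root / "loss.csv", index=False)
        with open(root / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype):
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(dtype)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64):
        self.W = Parameter(_glorot(rng, d_in, d_out, dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def params(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])


class MultiHeadAttention:
    """Bias-free multi-head self-attention over spots (Q = K = V = X)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 use_bias: bool = False, dtype=np.float64):
        if dim % heads != 0:
            raise ParameterError(
                f"embedding dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.d_k = dim, heads, dim // heads
        mk = lambda: Linear(dim, dim, rng, bias=use_bias, dtype=dtype)
        self.q, self.k, self.v, self.o = mk(), mk(), mk(), mk()

    def _split(self, t: Tensor, n: int) -> Tensor:
        return t.reshape(n, self.heads, self.d_k).transpose(1, 0, 2)

    def attention_scores(self, X: Tensor) -> Tensor:
        """(heads, N, N) softmax attention matrix; rows sum to 1."""
        n = X.shape[0]
        # fold the 1/sqrt(d_k) scale into q to avoid an extra N x N buffer
        q = self._split(self.q(X) * (1.0 / math.sqrt(self.d_k)), n)
        k = self._split(self.k(X), n)
        return (q @ k.transpose(0, 2, 1)).softmax(axis=-1)

    def __call__(self, X: Tensor) -> Tensor:
        n = X.shape[0]
        attn = self.attention_scores(X)
        v = self._split(self.v(X), n)
        mixed = (attn @ v).transpose(1, 0, 2).reshape(n, self.dim)
        return self.o(mixed)

    def params(self) -> list[Parameter]:
        return sum((m.params() for m in (self.q, self.k, self.v, self.o)), [])


class ResGatedGraphLayer:
    """Gated residual graph convolution.

    out_i = W1 h_i + sum_{j in N(i)} eta_ij * (W2 h_j) + b, with the edge
    gate eta_ij = sigmoid(W3 h_i + W4 h_j). The activation (ELU in the
    trunk, none for the mu / logvar heads) is applied by the caller.
    Isolated nodes receive only the self term.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64, gain: float = 1.0):
        self.W1 = Parameter(gain * _glorot(rng, d_in, d_out, dtype))
        self.W2 = Parameter(gain * _glorot(rng, d_in, d_out, dtype))
        self.W3 = Parameter(gain * _glorot(rng, d_in, d_out, dtype))
        self.W4 = Parameter(gain * _glorot(rng, d_in, d_out, dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype))

    def __call__(self, H: Tensor, edges: np.ndarray) -> Tensor:
        n = H.shape[0]
        out = H @ self.W1
        if edges.size:
            if edges.min() < 0 or edges.max() >= n:
                raise ConsistencyError("edge index out of range")
            dst, src = edges[:, 0], edges[:, 1]  # j in N(i): (i=dst, j=src)
            g_dst = (H @ self.W3).gather_rows(dst)
            g_src = (H @ self.W4).gather_rows(src)
            gate = (g_dst + g_src).sigmoid()
            msg = gate * (H @ self.W2).gather_rows(src)
            out = out + msg.scatter_add_rows(dst, n)
        return out + self.b

    def params(self) -> list[Parameter]:
        return [self.W1, self.W2, self.W3, self.W4, self.b]


# ---------------------------------------------------------------------------
# Functional pieces (numpy-facing)
# ---------------------------------------------------------------------------

def gated_graph_layer(H: np.ndarray, A: BinaryAdjacency,
                      layer: "ResGatedGraphLayer | None" = None,
                      d_out: int | None = None, seed: int = 0,
                      activation: bool = True) -> np.ndarray:
    """Apply one gated residual graph convolution to a numpy matrix.

    ``layer`` may carry hand-set parameters; otherwise one is seeded-random
    with output width ``d_out`` (default: input width). The ELU that follows
    the convolution in the trunk can be disabled for the variational heads.
    """
    H = np.asarray(H, dtype=float)
    if layer is None:
        rng = np.random.default_rng(seed)
        layer = ResGatedGraphLayer(H.shape[1], d_out or H.shape[1], rng)
    out = layer(Tensor(H), A.symmetrize().edges if not A.symmetrized else A.edges)
    return out.elu().data if activation else out.data


def multi_head_attention(X: np.ndarray, heads: int, params: dict | None = None,
                         use_bias: bool = False, seed: int = 0) -> np.ndarray:
    """Single attention stage on a numpy matrix (shape-preserving).

    ``params`` may supply projection matrices ``Wq, Wk, Wv, Wo`` explicitly
    (each D x D); otherwise they are seeded-random.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    mha = MultiHeadAttention(X.shape[1], heads, rng, use_bias=use_bias)
    if params is not None:
        for key, lin in (("Wq", mha.q), ("Wk", mha.k), ("Wv", mha.v), ("Wo", mha.o)):
            lin.W.data = np.asarray(params[key], dtype=float)
    return mha(Tensor(X)).data


def corrupt(Z_E: np.ndarray, sigma: float, rng, training: bool = True) -> np.ndarray:
    """Additive i.i.d. Gaussian corruption; identity in inference mode."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    Z_E = np.asarray(Z_E)
    if not training or sigma == 0:
        return Z_E.copy()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return Z_E + sigma * rng.standard_normal(Z_E.shape).astype(Z_E.dtype)


def reparameterize(mu, logvar, theta, mode: str = "standard"):
    """Latent sample from (mu, log sigma^2) and standard-normal noise theta.

    ``standard``: Z = mu + exp(logvar / 2) * theta.
    ``paper_literal``: Z = mu + logvar * theta (noise vanishes at logvar=0).
    Accepts numpy arrays or autodiff Tensors.
    """
    if mode == "standard":
        scale = (logvar * 0.5).exp() if isinstance(logvar, Tensor) \
            else np.exp(0.5 * np.asarray(logvar))
        return mu + scale * theta
    if mode == "paper_literal":
        return mu + logvar * theta
    raise ParameterError(f"unknown reparam mode {mode!r}")


def decode_adjacency(Z: np.ndarray) -> np.ndarray:
    """Inner-product edge probabilities sigmoid(Z Z^T); symmetric."""
    Z = np.asarray(Z, dtype=float)
    return 1.0 / (1.0 + np.exp(-(Z @ Z.T)))


def _bce_sample_support(A: BinaryAdjacency, seed: int
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Edges plus an equal-size seeded sample of non-edges (large-N path)."""
    rng = np.random.default_rng(seed)
    pos = A.edges
    existing = set(map(tuple, pos.tolist()))
    neg = []
    n = A.n
    while len(neg) < len(pos):
        i = rng.integers(0, n, size=len(pos))
        j = rng.integers(0, n, size=len(pos))
        for a, b in zip(i, j):
            if a != b and (a, b) not in existing and len(neg) < len(pos):
                neg.append((a, b))
    pairs = np.vstack([pos, np.array(neg, dtype=int)])
    targets = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return pairs, targets, 1.0


def _adj_bce_dense(p: np.ndarray, A: BinaryAdjacency) -> float:
    Y = A.to_dense()
    mask = 1.0 - np.eye(A.n)
    if mask.sum() == 0:  # single spot: no off-diagonal pairs to score
        return 0.0
    n_pos = Y.sum()
    n_neg = mask.sum() - n_pos
    w_pos = n_neg / n_pos if n_pos > 0 else 1.0
    pc = np.clip(p, _CLIP_LO, _CLIP_HI)
    terms = -(w_pos * Y * np.log(pc) + (1.0 - Y) * np.log(1.0 - pc))
    return float((terms * mask).sum() / mask.sum())


def compute_loss(X: np.ndarray, Xhat: np.ndarray, mu: np.ndarray,
                 logvar: np.ndarray, A: BinaryAdjacency, adj_probs: np.ndarray,
                 weights: tuple[float, float, float] = (1.0, 0.01, 0.1)
                 ) -> LossBreakdown:
    """Three-term loss on numpy arrays.

    * ``mse``: mean over all N*M entries of (Xhat - X)^2.
    * ``kl``: mean over spots of -1/2 * sum_dims(1 + logvar - mu^2 - exp(logvar)).
    * ``adj_bce``: binary cross-entropy of ``adj_probs`` (full N x N matrix)
      against the symmetrized adjacency on all off-diagonal pairs, with
      positive-class weight #non-edges / #edges. Probabilities are clipped
      to [1e-7, 1 - 1e-7] before the log.
    """
    X, Xhat = np.asarray(X, float), np.asarray(Xhat, float)
    mu, logvar = np.asarray(mu, float), np.asarray(logvar, float)
    if X.shape != Xhat.shape or mu.shape != logvar.shape:
        raise ConsistencyError("shape mismatch in loss inputs")
    mse = float(np.mean((Xhat - X) ** 2))
    kl = float(np.mean(-0.5 * np.sum(1.0 + logvar - mu ** 2 - np.exp(logvar),
                                     axis=1)))
    A = A.symmetrize()
    adj_bce = _adj_bce_dense(np.asarray(adj_probs, float), A)
    return LossBreakdown.combine(mse, kl, adj_bce, weights)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class VarggModel:
    """Assembled network; see the module docstring for the forward order."""

    def __init__(self, config: VarggConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        dt = config.np_dtype()
        M = config.input_dim
        h_in, h_mid, h_dec = config.attention_heads
        dims = list(config.dae_hidden_dims)
        if config.use_attention:
            self.attn_in = MultiHeadAttention(M, h_in, rng, dtype=dt)
            self.attn_mid = MultiHeadAttention(dims[0], h_mid, rng, dtype=dt)
            self.attn_dec = MultiHeadAttention(config.latent_dim, h_dec, rng, dtype=dt)
        else:
            self.attn_in = self.attn_mid = self.attn_dec = None
        # denoising encoder: M -> dims[0] -> ... -> G
        enc_dims = [M] + dims
        self.enc_layers = [Linear(a, b, rng, dtype=dt)
                           for a, b in zip(enc_dims[:-1], enc_dims[1:])]
        # graph trunk + variational heads
        g_dims = [config.latent_dim] + list(config.graph_hidden_dims)
        self.trunk = [ResGatedGraphLayer(a, b, rng, dtype=dt)
                      for a, b in zip(g_dims[:-1], g_dims[1:])]
        # small-gain init keeps mu near 0 and sigma^2 near 1 at the start,
        # the usual safe region for a variational head
        self.mu_head = ResGatedGraphLayer(g_dims[-1], config.latent_dim, rng,
                                          dtype=dt, gain=0.1)
        self.logvar_head = ResGatedGraphLayer(g_dims[-1], config.latent_dim, rng,
                                              dtype=dt, gain=0.1)
        # decoder: G -> reversed hidden -> M
        dec_dims = [config.latent_dim] + dims[-2::-1] + [M]
        self.dec_layers = [Linear(a, b, rng, dtype=dt)
                           for a, b in zip(dec_dims[:-1], dec_dims[1:])]

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        if self.attn_in is not None:
            for m in (self.attn_in, self.attn_mid, self.attn_dec):
                out += m.params()
        for lyr in self.enc_layers + self.trunk + [self.mu_head, self.logvar_head] \
                + self.dec_layers:
            out += lyr.params()
        return out

    def encode_dae(self, X: Tensor) -> Tensor:
        h = X
        for li, lyr in enumerate(self.enc_layers):
            h = lyr(h)
            if li == 0 and self.attn_mid is not None:
                h = self.attn_mid(h)
            if li < len(self.enc_layers) - 1:
                h = h.elu()
        return h

    def decode_dae(self, Z: Tensor, Z_E: Tensor) -> Tensor:
        h = Z + Z_E
        if self.attn_dec is not None:
            h = self.attn_dec(h)
        for li, lyr in enumerate(self.dec_layers):
            h = lyr(h)
            if li < len(self.dec_layers) - 1:
                h = h.elu()
        return h

    def latent_params(self, H0: Tensor, edges: np.ndarray) -> tuple[Tensor, Tensor]:
        h = H0
        for lyr in self.trunk:
            h = lyr(h, edges).elu()
        return self.mu_head(h, edges), self.logvar_head(h, edges)

    def forward(self, X: Tensor, edges: np.ndarray,
                noise: np.ndarray | None = None,
                theta: np.ndarray | None = None) -> dict:
        Xa = self.attn_in(X) if self.attn_in is not None else X
        Z_E = self.encode_dae(Xa)
        H0 = Z_E + Tensor(noise) if noise is not None else Z_E
        mu, logvar = self.latent_params(H0, edges)
        # clamp log-variance so exp() stays finite in float32
        logvar = logvar.clip(-10.0, 10.0)
        if theta is None:
            Z = mu
        else:
            Z = reparameterize(mu, logvar, Tensor(theta), self.config.reparam_mode)
        Xhat = self.decode_dae(Z, Z_E)
        return {"Xhat": Xhat, "mu": mu, "logvar": logvar, "Z": Z, "Z_E": Z_E}

    def loss(self, X: Tensor, out: dict, A_dense: np.ndarray | None,
             edges: np.ndarray, bce_support=None) -> tuple[Tensor, LossBreakdown]:
        cfg = self.config
        mw, kw, aw = cfg.loss_weights
        diff = out["Xhat"] - X
        mse = (diff * diff).mean()
        mu, logvar = out["mu"], out["logvar"]
        kl_terms = (1.0 + logvar - mu * mu - logvar.exp()) * (-0.5)
        kl = kl_terms.sum(axis=1).mean()
        Z = out["Z"]
        n = Z.shape[0]
        if A_dense is not None:
            mask = 1.0 - np.eye(n, dtype=A_dense.dtype)
            n_pos = float(A_dense.sum())
            n_neg = float(mask.sum() - n_pos)
            w_pos = n_neg / n_pos if n_pos > 0 else 1.0
            p = (Z @ Z.T).sigmoid().clip(_CLIP_LO, _CLIP_HI)
            terms = (p.log() * (-w_pos * A_dense)
                     + (1.0 - p).log() * (A_dense - 1.0))
            bce = (terms * mask).sum() * (1.0 / mask.sum())
        else:
            pairs, targets, w_pos = bce_support
            zi = Z.gather_rows(pairs[:, 0])
            zj = Z.gather_rows(pairs[:, 1])
            p = (zi * zj).sum(axis=1).sigmoid().clip(_CLIP_LO, _CLIP_HI)
            terms = p.log() * (-w_pos * targets) + (1.0 - p).log() * (targets - 1.0)
            bce = terms.mean()
        total = mse * mw + kl * kw + bce * aw
        breakdown = LossBreakdown.combine(float(mse.data), float(kl.data),
                                          float(bce.data), cfg.loss_weights)
        return total, breakdown


def fit(X: np.ndarray, A: BinaryAdjacency, config: VarggConfig) -> FitResult:
    """Train the network full-batch with Adam and return the fitted state.

    The adjacency is symmetrized (logical OR) before use; fresh corruption
    noise and reparameterization draws are made every epoch from seeded
    streams, so runs with the same config and seed are bit-identical. The
    returned ``latent`` is the posterior mean mu from a noise-free forward
    pass after the final epoch.
    """
    config.validate()
    X = np.asarray(X).astype(config.np_dtype())
    n = X.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 spots")
    if X.shape[1] != config.input_dim:
        config = VarggConfig(**{**asdict(config), "input_dim": X.shape[1]})
        config.validate()
    A = A.symmetrize()
    edges = A.edges
    dense = n <= config.bce_dense_limit
    A_dense = A.to_dense().astype(config.np_dtype()) if dense else None
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_init = np.random.default_rng(seeds[0])
    rng_noise = np.random.default_rng(seeds[1])
    rng_theta = np.random.default_rng(seeds[2])
    model = VarggModel(config, rng_init)
    opt = Adam(model.params(), lr=config.learning_rate)
    bce_support = None if dense else _bce_sample_support(A, config.seed)

    Xt = Tensor(X)
    trace: list[LossBreakdown] = []
    G = config.dae_hidden_dims[-1]
    for epoch in range(config.epochs):
        noise = (config.noise_sigma
                 * rng_noise.standard_normal((n, G)).astype(X.dtype)
                 if config.noise_sigma > 0 else None)
        theta = rng_theta.standard_normal((n, config.latent_dim)).astype(X.dtype)
        out = model.forward(Xt, edges, noise=noise, theta=theta)
        total, breakdown = model.loss(Xt, out, A_dense, edges, bce_support)
        for term, value in (("mse", breakdown.mse), ("kl", breakdown.kl),
                            ("adj_bce", breakdown.adj_bce)):
            if not np.isfinite(value):
                raise VarggError(
                    f"non-finite loss term {term!r} at epoch {epoch}")
        opt.zero_grad()
        total.backward()
        opt.step()
        trace.append(breakdown)

    out = model.forward(Xt, edges, noise=None, theta=None)  # inference pass
    mu = out["mu"].data.copy()
    probs = decode_adjacency(mu)
    edge_probs = probs[edges[:, 0], edges[:, 1]] if edges.size else np.empty(0)
    return FitResult(latent=mu, reconstruction=out["Xhat"].data.copy(),
                     adjacency_probs=edge_probs, loss_trace=trace,
                     config=config, seed=config.seed)
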