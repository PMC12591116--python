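"""Modality encoders: three linear layers, GELU, dropout, residual, and
per-sample standardization.

Both modalities (imaging features; SNP dosages concatenated with a one-hot
diagnosis block) share one architecture. For an input row x:

    h1 = x W1 + b1            (input_dim -> d)
    h2 = h1 W2 + b2           (d -> d)
    h3 = GELU(h2)
    h4 = Dropout(h3 W3 + b3)  (inverted dropout, active in train mode only)
    z  = h4 + h1              (residual connection)
    e  = (z - mean(z)) / std(z)   per-row, population std (eps-guarded)

so every embedding row has mean 0 and standard deviation 1 in eval mode.
All math is plain NumPy; gradients are derived analytically in `train`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .errors import DataError, NumericalError, UsageError

STANDARDIZE_EPS = 1e-8
_DEGENERATE_STD = 1e-12


def gelu(x):
    """Gaussian Error Linear Unit, exact form x * Phi(x) (erf, not tanh)."""
    x = np.asarray(x, dtype=float)
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def gelu_grad(x):
    """d/dx [x Phi(x)] = Phi(x) + x phi(x)."""
    x = np.asarray(x, dtype=float)
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


@dataclass
class EncoderParams:
    """One encoder's weights. Linear layers use the row-vector convention
    x W + b throughout."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    dropout_rate: float
    input_dim: int
    d: int

    def __post_init__(self):
        if self.d < 2:
            raise UsageError("embedding dimension d must be >= 2 "
                             "(per-sample standardization is undefined for d=1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise UsageError("dropout_rate must lie in [0, 1)")
        expected = {"W1": (self.input_dim, self.d), "b1": (self.d,),
                    "W2": (self.d, self.d), "b2": (self.d,),
                    "W3": (self.d, self.d), "b3": (self.d,)}
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise UsageError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in ("W1", "b1", "W2", "b2", "W3", "b3")}


@dataclass
class EmbeddingBatch:
    """A batch of embedding rows for one modality."""

    matrix: np.ndarray            # (B, d)
    modality: str                 # "image" | "snp_label"
    mode: str                     # "train" | "eval"


def init_params(input_dim: int, d: int, dropout_rate: float = 0.1,
                seed: int = 0) -> EncoderParams:
    """Scaled-uniform initialization: each weight matrix drawn from
    U(-1/sqrt(fan_in), 1/sqrt(fan_in)); biases zero. Deterministic per seed."""
    if input_dim < 1:
        raise UsageError("input_dim must be positive")
    if d < 2:
        raise UsageError("embedding dimension d must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1417]))

    def draw(fan_in, shape):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return EncoderParams(
        W1=draw(input_dim, (input_dim, d)), b1=np.zeros(d),
        W2=draw(d, (d, d)), b2=np.zeros(d),
        W3=draw(d, (d, d)), b3=np.zeros(d),
        dropout_rate=float(dropout_rate), input_dim=int(input_dim), d=int(d),
    )


def standardize_rows(Z: np.ndarray) -> np.ndarray:
    """Per-row standardization (population std, ddof=0).

    Rows with std below the degenerate threshold are fatal rather than
    eps-smoothed, so the operation is exactly idempotent on valid input.
    """
    mu = Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    degenerate = np.flatnonzero(sd[:, 0] < _DEGENERATE_STD)
    if degenerate.size:
        raise NumericalError(
            f"embedding row {degenerate[0]} is constant (std < {_DEGENERATE_STD:g}); "
            "cannot standardize")
    return (Z - mu) / np.maximum(sd, STANDARDIZE_EPS)


def encode_forward(X: np.ndarray, params: EncoderParams, mode: str = "eval",
                   rng: np.random.Generator | None = None,
                   modality: str = "image", return_cache: bool = False):
    """Run the encoder on a batch of input rows.

    Dropout is active only in train mode (inverted scaling, so eval mode needs
    no rescaling and is rng-independent). With return_cache=True the
    intermediates needed for backpropagation are returned alongside.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.input_dim:
        raise UsageError(f"input has {X.shape[1]} columns, encoder expects "
                         f"{params.input_dim}")
    if mode not in ("train", "eval"):
        raise UsageError(f"mode must be 'train' or 'eval', got {mode!r}")
    if not np.isfinite(X).all():
        raise DataError("non-finite values in encoder input")

    h1 = X @ params.W1 + params.b1
    h2 = h1 @ params.W2 + params.b2
    h3 = gelu(h2)
    a = h3 @ params.W3 + params.b3
    if mode == "train" and params.dropout_rate > 0.0:
        if rng is None:
            raise UsageError("train mode with dropout requires an rng")
        keep = 1.0 - params.dropout_rate
        mask = (rng.random(a.shape) < keep) / keep
    else:
        mask = np.ones_like(a)
    h4 = a * mask
    z = h4 + h1

    mu = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    degenerate = np.flatnonzero(sd[:, 0] < _DEGENERATE_STD)
    if degenerate.size:
        raise NumericalError(
            f"embedding row {degenerate[0]} of the batch is constant; "
            "cannot standardize")
    e = (z - mu) / np.maximum(sd, STANDARDIZE_EPS)

    batch = EmbeddingBatch(matrix=e, modality=modality, mode=mode)
    if not return_cache:
        return batch
    cache = {"X": X, "h1": h1, "h2": h2, "h3": h3, "mask": mask,
             "z": z, "mu": mu, "sd": sd}
    return batch, cache


def encoder_backward(dE: np.ndarray, cache: dict, params: EncoderParams):
    """Backpropagate dLoss/dE through one encoder.

    Returns a dict of parameter gradients keyed like EncoderParams.arrays().
    """
    z, mu, sd = cache["z"], cache["mu"], cache["sd"]
    c = z - mu
    denom = np.maximum(sd, STANDARDIZE_EPS)
    # e = c / denom with sd = sqrt(mean(c^2)):
    # dL/dz_k = (g_k - mean(g)) / sd - c_k mean(g c) / sd^3
    g_mean = dE.mean(axis=1, keepdims=True)
    gc_mean = (dE * c).mean(axis=1, keepdims=True)
    dz = (dE - g_mean) / denom - c * gc_mean / denom ** 3

    dh4 = dz
    dh1 = dz.copy()
    da = dh4 * cache["mask"]
    dW3 = cache["h3"].T @ da
    db3 = da.sum(axis=0)
    dh3 = da @ params.W3.T
    dh2 = dh3 * gelu_grad(cache["h2"])
    dW2 = cache["h1"].T @ dh2
    db2 = dh2.sum(axis=0)
    dh1 += dh2 @ params.W2.T
    dW1 = cache["X"].T @ dh1
    db1 = dh1.sum(axis=0)
    return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2, "W3": dW3, "b3": db3}


# ---------------------------------------------------------------------------
# Parameter (de)serialization helpers used by the model checkpoint
# ---------------------------------------------------------------------------

def params_to_dict(p: EncoderParams, prefix: str) -> dict[str, np.ndarray]:
    out = {f"{prefix}_{k}": v for k, v in p.arrays().items()}
    out[f"{prefix}_meta"] = np.array(
        json.dumps({"dropout_rate": p.dropout_rate,
                    "input_dim": p.input_dim, "d": p.d}))
    return out


def params_from_dict(data, prefix: str) -> EncoderParams:
    try:
        meta = json.loads(str(data[f"{prefix}_meta"]))
        arrays = {k: np.asarray(data[f"{prefix}_{k}"], dtype=float)
                  for k in ("W1", "b1", "W2", "b2", "W3", "b3")}
    except KeyError as exc:
        raise DataError(f"checkpoint is missing encoder field {exc}") from exc
    return EncoderParams(**arrays, **meta)
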