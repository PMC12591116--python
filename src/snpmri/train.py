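"""Temperature-scaled contrastive alignment of the two modality encoders.

The objective is the image-anchored InfoNCE form: for a batch of B paired
embeddings (image e_{t,i}; SNP-label e_{t,s}),

    sim(u, v) = (u . v) / tau
    L = (1/B) sum_t -log[ exp(sim(e_{t,i}, e_{t,s}))
                          / sum_{t'} exp(sim(e_{t,i}, e_{t',s})) ]

i.e. a softmax over the SNP-side candidates of the whole batch, anchored on
each image embedding (one-directional; a symmetric two-directional variant is
available behind `TrainConfig.symmetric`). Similarities are plain dot
products — rows are already per-sample standardized by the encoders.

Gradients are computed analytically (softmax backward through the encoder
chain) and optimized with Adam. Everything is reproducible from the config
seed via named substreams (init / shuffle / dropout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp

from .cohort import CohortTable, SplitIndex
from .encoder import (EncoderParams, encode_forward, encoder_backward,
                      init_params, params_from_dict, params_to_dict)
from .errors import DataError, NumericalError, UsageError

CHECKPOINT_VERSION = 1

_SUB_IMG_INIT = 11
_SUB_SNP_INIT = 12
_SUB_SHUFFLE = 13
_SUB_DROPOUT = 14


@dataclass
class TrainConfig:
    """Alignment-training hyperparameters.

    temperature: softmax temperature tau (> 0) dividing similarity scores.
    d: shared embedding dimension of both encoders.
    symmetric: also anchor on the SNP side and average the two losses.
    """

    temperature: float = 0.07
    batch_size: int = 64
    epochs: int = 600
    learning_rate: float = 1e-3
    seed: int = 0
    d: int = 128
    dropout_rate: float = 0.1
    symmetric: bool = False

    def validate(self) -> None:
        if self.temperature <= 0:
            raise UsageError("temperature must be positive")
        if self.batch_size < 1:
            raise UsageError("batch_size must be >= 1")
        if self.epochs < 1:
            raise UsageError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise UsageError("learning_rate must be positive")


@dataclass
class AlignmentModel:
    """Trained encoder pair plus the preprocessing state needed at inference."""

    image_encoder: EncoderParams
    snp_encoder: EncoderParams
    config: TrainConfig
    classes: tuple[str, ...]
    imaging_mean: np.ndarray
    imaging_sd: np.ndarray
    geno_mean: np.ndarray
    geno_sd: np.ndarray
    snp_ids: list[str]
    roi_ids: list[str]
    loss_history: list[float] = field(default_factory=list)
    val_loss_history: list[float] = field(default_factory=list)

    @property
    def trained(self) -> bool:
        return len(self.loss_history) > 0

    # -- inference-time encoders ------------------------------------------

    def scale_imaging(self, imaging: np.ndarray) -> np.ndarray:
        return (np.asarray(imaging, dtype=float) - self.imaging_mean) / self.imaging_sd

    def snp_input(self, genotypes: np.ndarray, labels=None) -> np.ndarray:
        """Standardized dosage block concatenated with the one-hot diagnosis
        block; when labels is None the label slots are zeroed (inference
        convention, so SNP-side embeddings can never leak the diagnosis)."""
        G = np.atleast_2d(np.asarray(genotypes, dtype=float))
        G = (G - self.geno_mean) / self.geno_sd
        onehot = np.zeros((G.shape[0], len(self.classes)))
        if labels is not None:
            lab = np.asarray(labels, dtype=object)
            for k, cls in enumerate(self.classes):
                onehot[lab == cls, k] = 1.0
        return np.hstack([G, onehot])

    def encode_image(self, imaging: np.ndarray) -> np.ndarray:
        return encode_forward(self.scale_imaging(imaging), self.image_encoder,
                              mode="eval", modality="image").matrix

    def encode_snp(self, genotypes: np.ndarray, labels=None) -> np.ndarray:
        return encode_forward(self.snp_input(genotypes, labels), self.snp_encoder,
                              mode="eval", modality="snp_label").matrix


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def similarity(e_i: np.ndarray, e_s: np.ndarray, tau: float) -> float:
    """Temperature-scaled dot product between two embedding vectors."""
    if tau <= 0:
        raise UsageError("temperature must be positive")
    e_i = np.asarray(e_i, dtype=float)
    e_s = np.asarray(e_s, dtype=float)
    if e_i.shape != e_s.shape:
        raise UsageError("embedding dimensions differ")
    return float(e_i @ e_s) / tau


def _similarity_matrix(E_img, E_snp, tau):
    if tau <= 0:
        raise UsageError("temperature must be positive")
    E_img = np.atleast_2d(np.asarray(E_img, dtype=float))
    E_snp = np.atleast_2d(np.asarray(E_snp, dtype=float))
    if E_img.shape != E_snp.shape:
        raise UsageError(f"batch shapes differ: {E_img.shape} vs {E_snp.shape}")
    if E_img.shape[0] == 0:
        raise UsageError("empty batch")
    if not (np.isfinite(E_img).all() and np.isfinite(E_snp).all()):
        raise DataError("non-finite embedding entries")
    return E_img @ E_snp.T / tau


def contrastive_loss(E_img: np.ndarray, E_snp: np.ndarray, tau: float) -> float:
    """Image-anchored batch contrastive loss (max-shifted for overflow safety)."""
    S = _similarity_matrix(E_img, E_snp, tau)
    return float(np.mean(logsumexp(S, axis=1) - np.diag(S)))


def contrastive_loss_grad(E_img: np.ndarray, E_snp: np.ndarray, tau: float,
                          symmetric: bool = False):
    """Loss plus its analytic gradients w.r.t. both embedding matrices."""
    S = _similarity_matrix(E_img, E_snp, tau)
    B = S.shape[0]
    P = np.exp(S - logsumexp(S, axis=1, keepdims=True))
    loss = float(np.mean(logsumexp(S, axis=1) - np.diag(S)))
    dS = (P - np.eye(B)) / B
    if symmetric:
        # average with the SNP-anchored direction (softmax over columns)
        Pt = np.exp(S - logsumexp(S, axis=0, keepdims=True))
        loss = 0.5 * (loss + float(np.mean(logsumexp(S, axis=0) - np.diag(S))))
        dS = 0.5 * (dS + (Pt - np.eye(B)) / B)
    dE_img = dS @ E_snp / tau
    dE_snp = dS.T @ E_img / tau
    return loss, dE_img, dE_snp


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam over a dict of parameter arrays."""

    def __init__(self, shapes: dict[str, tuple], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c)
                                                        + self.eps)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _sub_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def train_alignment(cohort: CohortTable, split: SplitIndex,
                    config: TrainConfig) -> AlignmentModel:
    """Fit both encoders by minibatch Adam on the contrastive objective.

    Imaging features are z-scored with training-split statistics (stored on
    the model); dosages enter raw. The SNP-side input carries the one-hot
    diagnosis block during training. Per-epoch mean training loss and
    eval-mode validation loss are recorded.
    """
    config.validate()
    train_idx = split.indices("train")
    if train_idx.size == 0:
        raise DataError("training split is empty")
    if config.batch_size > train_idx.size:
        raise UsageError(f"batch_size {config.batch_size} exceeds training-set "
                         f"size {train_idx.size}")

    classes = cohort.classes
    img_mean = cohort.imaging[train_idx].mean(axis=0)
    img_sd = cohort.imaging[train_idx].std(axis=0)
    img_sd[img_sd < 1e-12] = 1.0
    geno_mean = cohort.genotypes[train_idx].mean(axis=0)
    geno_sd = cohort.genotypes[train_idx].std(axis=0)
    geno_sd[geno_sd < 1e-12] = 1.0

    model = AlignmentModel(
        image_encoder=init_params(len(cohort.roi_ids), config.d,
                                  config.dropout_rate,
                                  seed=_mix(config.seed, _SUB_IMG_INIT)),
        snp_encoder=init_params(len(cohort.snp_ids) + len(classes), config.d,
                                config.dropout_rate,
                                seed=_mix(config.seed, _SUB_SNP_INIT)),
        config=config, classes=classes, imaging_mean=img_mean, imaging_sd=img_sd,
        geno_mean=geno_mean, geno_sd=geno_sd,
        snp_ids=list(cohort.snp_ids), roi_ids=list(cohort.roi_ids),
    )

    X_img = model.scale_imaging(cohort.imaging)
    X_snp = model.snp_input(cohort.genotypes, cohort.labels)
    val_idx = split.indices("validation")

    shapes = {f"img_{k}": v.shape for k, v in model.image_encoder.arrays().items()}
    shapes |= {f"snp_{k}": v.shape for k, v in model.snp_encoder.arrays().items()}
    opt = Adam(shapes, lr=config.learning_rate)
    params = {f"img_{k}": v for k, v in model.image_encoder.arrays().items()}
    params |= {f"snp_{k}": v for k, v in model.snp_encoder.arrays().items()}

    shuffle_rng = _sub_rng(config.seed, _SUB_SHUFFLE)
    drop_rng = _sub_rng(config.seed, _SUB_DROPOUT)

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(train_idx)
        total, count = 0.0, 0
        for start in range(0, order.size, config.batch_size):
            batch = order[start:start + config.batch_size]
            eb_i, cache_i = encode_forward(X_img[batch], model.image_encoder,
                                           mode="train", rng=drop_rng,
                                           modality="image", return_cache=True)
            eb_s, cache_s = encode_forward(X_snp[batch], model.snp_encoder,
                                           mode="train", rng=drop_rng,
                                           modality="snp_label", return_cache=True)
            loss, dEi, dEs = contrastive_loss_grad(
                eb_i.matrix, eb_s.matrix, config.temperature,
                symmetric=config.symmetric)
            if not np.isfinite(loss):
                raise NumericalError(f"training loss diverged at epoch {epoch}")
            gi = encoder_backward(dEi, cache_i, model.image_encoder)
            gs = encoder_backward(dEs, cache_s, model.snp_encoder)
            grads = {f"img_{k}": v for k, v in gi.items()}
            grads |= {f"snp_{k}": v for k, v in gs.items()}
            opt.step(params, grads)
            total += loss * batch.size
            count += batch.size
        model.loss_history.append(total / count)

        if val_idx.size >= 2:
            ev_i = encode_forward(X_img[val_idx], model.image_encoder, mode="eval")
            ev_s = encode_forward(X_snp[val_idx], model.snp_encoder, mode="eval")
            model.val_loss_history.append(
                contrastive_loss(ev_i.matrix, ev_s.matrix, config.temperature))
    return model


def _mix(seed: int, tag: int) -> int:
    # stable derived seed below 2^31 for the encoder init substreams
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] % (2**31))


def retrieval_accuracy(model: AlignmentModel, cohort_subset: CohortTable,
                       k: int = 1, use_labels: bool = True) -> float:
    """Fraction of subjects whose own SNP-side embedding is among the k most
    similar to their image embedding (eval mode).

    `use_labels` feeds the one-hot diagnosis block as during training; set
    False to probe the inference-time (label-free) embeddings.
    """
    n = cohort_subset.n_subjects
    if n < 2:
        raise UsageError("retrieval needs at least 2 subjects")
    if k >= n:
        raise UsageError(f"k={k} >= subset size {n}: retrieval would be trivial")
    E_i = model.encode_image(cohort_subset.imaging)
    E_s = model.encode_snp(cohort_subset.genotypes,
                           cohort_subset.labels if use_labels else None)
    S = E_i @ E_s.T
    # rank of the diagonal entry within its row (0 = most similar)
    ranks = (S > np.diag(S)[:, None]).sum(axis=1)
    return float(np.mean(ranks < k))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: AlignmentModel, path) -> None:
    """Write a versioned checkpoint (parameter arrays + JSON config block)."""
    data = params_to_dict(model.image_encoder, "img")
    data |= params_to_dict(model.snp_encoder, "snp")
    data["version"] = np.array(CHECKPOINT_VERSION)
    data["config"] = np.array(json.dumps(asdict(model.config)))
    data["classes"] = np.array(json.dumps(list(model.classes)))
    data["imaging_mean"] = model.imaging_mean
    data["imaging_sd"] = model.imaging_sd
    data["geno_mean"] = model.geno_mean
    data["geno_sd"] = model.geno_sd
    data["snp_ids"] = np.array(json.dumps(model.snp_ids))
    data["roi_ids"] = np.array(json.dumps(model.roi_ids))
    data["loss_history"] = np.asarray(model.loss_history, dtype=float)
    data["val_loss_history"] = np.asarray(model.val_loss_history, dtype=float)
    np.savez(path, **data)


def load_model(path) -> AlignmentModel:
    """Load a checkpoint written by `save_model`; bit-exact round trip."""
    try:
        with np.load(path, allow_pickle=False) as data:
            version = int(data["version"])
            if version != CHECKPOINT_VERSION:
                raise DataError(f"checkpoint version {version} is not supported "
                                f"(expected {CHECKPOINT_VERSION})")
            return AlignmentModel(
                image_encoder=params_from_dict(data, "img"),
                snp_encoder=params_from_dict(data, "snp"),
                config=TrainConfig(**json.loads(str(data["config"]))),
                classes=tuple(json.loads(str(data["classes"]))),
                imaging_mean=np.asarray(data["imaging_mean"], dtype=float),
                imaging_sd=np.asarray(data["imaging_sd"], dtype=float),
                geno_mean=np.asarray(data["geno_mean"], dtype=float),
                geno_sd=np.asarray(data["geno_sd"], dtype=float),
                snp_ids=json.loads(str(data["snp_ids"])),
                roi_ids=json.loads(str(data["roi_ids"])),
                loss_history=list(map(float, data["loss_history"])),
                val_loss_history=list(map(float, data["val_loss_history"])),
            )
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"cannot load model checkpoint {path}: {exc}") from exc
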