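"""Dataset construction and the training loop.

Training examples pair a decoy with per-nucleotide lDDT labels computed
against its native by the lddt module (undefined nucleotides are masked
out of the loss). The network is trained with Adam on the mean absolute
error between pNuL and the labels, pooled over all unmasked nucleotides.
One structure per optimisation step (variable chain lengths make padding
wasteful); global gradient-norm clipping at 1.0 for stability. A fixed
seed reproduces the loss trace bit-exactly on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lddt as lddt_mod
from .autodiff import Tensor
from .network import ModelConfig, forward, init_model, structure_inputs
from .structure_io import RNAStructure, read_structure


class DivergedError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainingExample:
    decoy: RNAStructure
    native_id: str
    labels: np.ndarray           # per-nucleotide lDDT, NaN where undefined
    mask: np.ndarray             # True where the label is defined
    truth_global: float          # pooled lDDT of the decoy (for evaluation)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 50
    batch: int = 1
    seed: int = 0
    grad_clip: float = 1.0
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch < 1:
            raise ValueError("learning rate, epochs and batch must be positive")


def build_dataset(natives: dict[str, RNAStructure], decoys: list[RNAStructure],
                  pairing: dict[str, str]) -> list[TrainingExample]:
    """Label every decoy against its paired native; deterministic ordering
    by (native id, decoy id)."""
    examples = []
    for decoy in decoys:
        if decoy.id not in pairing:
            raise ValueError(f"unpaired decoy: {decoy.id}")
        native = natives[pairing[decoy.id]]
        scores = lddt_mod.per_nucleotide_lddt(decoy, native)
        examples.append(TrainingExample(
            decoy=decoy, native_id=native.id,
            labels=scores.per_nucleotide, mask=scores.defined,
            truth_global=scores.global_,
        ))
    examples.sort(key=lambda ex: (ex.native_id, ex.decoy.id))
    return examples


def dataset_from_manifest(manifest) -> list[TrainingExample]:
    """Read the PDB files of a decoy manifest and label them."""
    natives = {nid: read_structure(path, structure_id=nid)
               for nid, path in manifest.native_paths.items()}
    decoys, pairing = [], {}
    for rec in manifest.decoys:
        decoys.append(read_structure(rec.path, structure_id=rec.decoy_id))
        pairing[rec.decoy_id] = rec.native_id
    return build_dataset(natives, decoys, pairing)


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> dict[str, np.ndarray]:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        return {k: g * scale for k, g in grads.items()}
    return grads


def masked_mae(pnul: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean absolute error over unmasked nucleotides (autodiff scalar)."""
    idx = np.flatnonzero(mask)
    return (pnul[idx] - Tensor(labels[idx])).abs().mean()


def train(dataset: list[TrainingExample], model_config: ModelConfig,
          train_config: TrainConfig,
          validation: list[TrainingExample] | None = None,
          log=None):
    """Train from scratch; returns (params, epoch_trace).

    The trace holds one dict per epoch with the pooled training MAE (and
    validation MAE when a validation split is supplied; the best-validation
    parameter set is what gets returned in that case).
    """
    if not dataset:
        raise ValueError("dataset is empty")
    params = init_model(model_config, train_config.seed)
    opt = Adam(params, train_config.learning_rate, train_config.betas)
    rng = np.random.default_rng(train_config.seed + 1)

    cache = [(ex, structure_inputs(ex.decoy, model_config)) for ex in dataset]
    val_cache = ([(ex, structure_inputs(ex.decoy, model_config)) for ex in validation]
                 if validation else None)

    trace: list[dict] = []
    best = None
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(cache))
        abs_sum, n_sum = 0.0, 0
        for step, ci in enumerate(order):
            ex, (node, edge, nbr, R, t) = cache[ci]
            pnul = forward(params, model_config, node, edge, nbr, R, t, rng=rng)
            loss = masked_mae(pnul, ex.labels, ex.mask)
            if not np.isfinite(loss.data):
                raise DivergedError(f"diverged: non-finite loss at epoch {epoch}")
            for p in params.values():
                p.grad = None
            loss.backward()
            grads = _clip_grads({k: p.grad for k, p in params.items()},
                                train_config.grad_clip)
            opt.step(grads)
            n = int(ex.mask.sum())
            abs_sum += float(loss.data) * n
            n_sum += n
        entry = {"epoch": epoch + 1, "train_mae": abs_sum / n_sum}
        if val_cache is not None:
            entry["val_mae"] = _eval_mae(params, model_config, val_cache)
            if best is None or entry["val_mae"] < best[0]:
                best = (entry["val_mae"], {k: p.data.copy() for k, p in params.items()})
        trace.append(entry)
        if log is not None:
            log(entry)
    if best is not None:
        for k, p in params.items():
            p.data = best[1][k]
    return params, trace


def _eval_mae(params, model_config, cache) -> float:
    abs_sum, n_sum = 0.0, 0
    for ex, (node, edge, nbr, R, t) in cache:
        pnul = forward(params, model_config, node, edge, nbr, R, t, rng=None)
        err = np.abs(pnul.data[ex.mask] - ex.labels[ex.mask])
        abs_sum += float(err.sum())
        n_sum += err.size
    return abs_sum / n_sum


def evaluate_mae(params, model_config, dataset: list[TrainingExample]) -> float:
    """Pooled inference-mode MAE of pNuL against the labels."""
    cache = [(ex, structure_inputs(ex.decoy, model_config)) for ex in dataset]
    return _eval_mae(params, model_config, cache)
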