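"""Training, inference and evaluation of realized segmentation networks.

Protocol defaults follow the method's training recipe: Adam with default
betas at learning rate 0.001, batch size 1, 100 epochs, dropout 0.2,
batch normalization, inverse-frequency weighted cross-entropy.  The best
checkpoint is selected on validation mean Dice.  Training is
deterministic for a fixed seed on a single CPU thread (best-effort).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import losses as L
from .arch import NetworkSpec
from .backend.network import Adam, ExecutableNetwork, realize
from .backend.tape import Tensor, softmax_channels
from .metrics import MetricReport, evaluate_set


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    batch_size: int = 1
    epochs: int = 100
    dropout: float = 0.2
    loss: str = "weighted_ce"
    seed: int = 0
    device: str = "cpu"
    max_steps: int | None = None  # optional hard cap on optimization steps
    freq_floor: float = L.FREQ_FLOOR

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in L.LOSSES:
            raise ValueError(f"loss must be one of {sorted(L.LOSSES)}")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")
        if self.device not in ("cpu", "accelerator"):
            raise ValueError("device must be 'cpu' or 'accelerator'")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mean_di: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TrainingHistory":
        return cls(**json.loads(text))


def _loss_and_grad(probs_nchw: np.ndarray, labels: np.ndarray,
                   loss_name: str, freqs: L.ClassFrequencies | None):
    """Loss value and d(loss)/d(logits) in NCHW layout."""
    probs = probs_nchw[0].transpose(1, 2, 0)  # (H, W, n_classes)
    if loss_name == "weighted_ce":
        value = L.weighted_cross_entropy(probs, labels, freqs).value
        grad = L.weighted_cross_entropy_grad(probs, labels, freqs)
    elif loss_name == "ce":
        value = L.cross_entropy(probs, labels).value
        grad = L.cross_entropy_grad(probs, labels)
    else:
        value = L.dice_loss(probs, labels).value
        grad = L.dice_loss_grad(probs, labels)
    return value, grad.transpose(2, 0, 1)[None].astype(np.float32)


def _eval_loss(net: ExecutableNetwork, data, loss_name: str,
               freqs_of=None) -> float:
    total = 0.0
    for image, mask in data:
        probs = net(image, training=False)
        if loss_name == "weighted_ce":
            fr = freqs_of(mask) if freqs_of else L.class_frequencies(mask)
            total += L.weighted_cross_entropy(probs, mask, fr).value
        elif loss_name == "ce":
            total += L.cross_entropy(probs, mask).value
        else:
            total += L.dice_loss(probs, mask).value
    return total / len(data)


def train(spec: NetworkSpec, train_data, val_data=None,
          cfg: TrainConfig | None = None,
          dataset_freqs: L.ClassFrequencies | None = None):
    """Train a realized network; returns ``(best_weights, history)``.

    ``train_data``/``val_data`` are lists of ``(image, mask)`` pairs
    already preprocessed to the spec's input side.  Class frequencies
    for the weighted loss are computed per image unless
    ``dataset_freqs`` is supplied.  The checkpoint with the best
    validation mean Dice is returned (final weights when no validation
    set is given).
    """
    cfg = cfg or TrainConfig()
    train_data = list(train_data)
    if not train_data:
        raise ValueError("empty training dataset")
    val_data = list(val_data) if val_data else []

    net = realize(spec, seed=cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainingHistory()
    best_di = -1.0
    best_weights = net.state_dict()
    steps = 0
    done = False

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_data))
        epoch_losses = []
        for idx in order:
            image, mask = train_data[idx]
            x = Tensor(np.asarray(image, dtype=np.float32)[None, None])
            logits = net.forward(x, training=True)
            probs = softmax_channels(logits.data)
            freqs = dataset_freqs
            if cfg.loss == "weighted_ce" and freqs is None:
                freqs = L.class_frequencies(mask, floor=cfg.freq_floor)
            value, grad = _loss_and_grad(probs, mask, cfg.loss, freqs)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at step {steps} (epoch {epoch}); "
                    "try a lower learning rate")
            epoch_losses.append(value)
            opt.zero_grad()
            logits.backward(grad)
            opt.step()
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                done = True
                break
        history.train_loss.append(float(np.mean(epoch_losses)))

        if val_data:
            history.val_loss.append(
                _eval_loss(net, val_data, cfg.loss))
            pairs = [(predict(net, img), msk) for img, msk in val_data]
            report = evaluate_set(pairs)
            history.val_mean_di.append(report.mean_di)
            if report.mean_di > best_di:
                best_di = report.mean_di
                history.best_epoch = epoch
                best_weights = net.state_dict()
        else:
            history.best_epoch = epoch
            best_weights = net.state_dict()
        if done:
            break

    return best_weights, history


def predict(net: ExecutableNetwork, image: np.ndarray,
            original_size: tuple[int, int] | None = None) -> np.ndarray:
    """Binary mask prediction: per-pixel argmax, optionally resized back
    (nearest neighbor) to ``original_size`` = (width, height)."""
    probs = net(image, training=False)
    mask = (np.argmax(probs, axis=-1) == 1).astype(np.uint8)
    if original_size is not None:
        w, h = original_size
        if (h, w) != mask.shape:
            mask = _sk_resize(mask, (h, w), order=0, preserve_range=True,
                              anti_aliasing=False).astype(np.uint8)
    return mask


def evaluate(net: ExecutableNetwork, dataset, ids=None,
             csv_path=None) -> MetricReport:
    """Evaluate a network on ``(image, mask)`` pairs; optional CSV report."""
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty evaluation dataset")
    for i, (_, mask) in enumerate(dataset):
        if mask is None:
            raise ValueError(f"sample {i} has no ground-truth mask")
    pairs = [(predict(net, img), mask) for img, mask in dataset]
    report = evaluate_set(pairs, ids=ids)
    if csv_path is not None:
        report.to_csv(csv_path)
    return report


def save_checkpoint(path, spec: NetworkSpec, weights: dict) -> None:
    """Self-describing checkpoint: weights plus the embedded spec."""
    path = Path(path)
    np.savez_compressed(path, __spec_json__=np.frombuffer(
        spec.to_json().encode(), dtype=np.uint8),
        **weights)


def load_checkpoint(path, seed: int = 0):
    """Load a checkpoint; returns ``(spec, network)`` ready for inference."""
    with np.load(Path(path)) as data:
        spec = NetworkSpec.from_json(
            bytes(data["__spec_json__"]).decode())
        weights = {k: data[k] for k in data.files if k != "__spec_json__"}
    net = realize(spec, seed=seed)
    net.load_state_dict(weights)
    return spec, net
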