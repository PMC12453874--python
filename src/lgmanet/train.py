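"""Training regime, evaluation, checkpointing, and the ablation sweep.

Optimisation is Adam on the Dice loss of the sigmoid-activated final output
(no auxiliary losses at intermediate stages), with a cosine-annealed
learning rate stepped once per epoch and seeded shuffled batching. A run is
fully reproducible from (seed, configs, data).
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import (DatasetSpec, ModelConfig, SynthSpec, TrainConfig,
                     VARIANTS, config_to_dict)
from .data import SamplePair, augment, load_split, split_stems, synth_pairs
from .metrics import MetricsReport, dice_loss
from .network import LgmaNet, build_model, make_variant
from .nn import Tensor


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate at the start of `epoch` (0-based).

    lr = lr_min + (lr0 - lr_min) * (1 + cos(pi * epoch / epochs)) / 2.
    """
    if not (0 <= epoch <= cfg.epochs):
        raise ValueError(f"epoch must lie in [0, {cfg.epochs}], got {epoch}")
    cos = np.cos(np.pi * epoch / cfg.epochs)
    return cfg.lr_min + 0.5 * (cfg.lr0 - cfg.lr_min) * (1.0 + cos)


@dataclass
class RunRecord:
    """Per-epoch training trace plus the final evaluation report."""
    epochs: list[dict] = field(default_factory=list)  # {epoch, loss, lr}
    final_metrics: MetricsReport | None = None
    checkpoint_path: str | None = None

    @property
    def final_loss(self) -> float:
        return self.epochs[-1]["loss"] if self.epochs else float("nan")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(("epoch", "loss", "lr"))
            for e in self.epochs:
                wr.writerow((e["epoch"], e["loss"], e["lr"]))

    def to_json(self, path) -> None:
        doc = {"epochs": self.epochs, "checkpoint": self.checkpoint_path}
        if self.final_metrics is not None:
            doc["final_aggregate"] = self.final_metrics.aggregate
        Path(path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------
# data resolution
# ---------------------------------------------------------------------

def resolve_data(data, holdout: bool = True) -> tuple[list[SamplePair], list[SamplePair]]:
    """Turn a DatasetSpec / SynthSpec / list of pairs into (train, test).

    With ``holdout=False`` (e.g. an overfit fixture) the test set is the
    training set itself.
    """
    if isinstance(data, DatasetSpec):
        train_pairs, test_pairs = load_split(data)
    elif isinstance(data, SynthSpec):
        pairs = synth_pairs(data)
        if holdout and data.n_images >= 2:
            stems = [p.stem for p in pairs]
            by_stem = {p.stem: p for p in pairs}
            tr, te = split_stems(stems, 0.8, data.seed)
            train_pairs = [by_stem[s] for s in tr]
            test_pairs = [by_stem[s] for s in te]
        else:
            train_pairs, test_pairs = pairs, pairs
    elif isinstance(data, (list, tuple)):
        train_pairs = list(data)
        test_pairs = list(data)
    else:
        raise TypeError(f"unsupported data source: {type(data)!r}")
    if not train_pairs:
        raise ValueError("training set is empty")
    if not holdout:
        test_pairs = train_pairs
    return train_pairs, test_pairs


def _stack(pairs: list[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.image for p in pairs]).astype(np.float32)
    y = np.stack([p.mask for p in pairs]).astype(np.float32)
    return x, y


# ---------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------

def save_checkpoint(model: LgmaNet, path) -> Path:
    """Weights to <path>.npz; ModelConfig manifest to <path>.manifest.json."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    manifest = {"format_version": 1, "model_config": config_to_dict(model.cfg)}
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path) -> LgmaNet:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".manifest.json").read_text())
    cfg_dict = manifest["model_config"]
    for key in ("stage_widths", "lgipb_inner_widths", "emra_kernel_sizes"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = LgmaNet(ModelConfig(**cfg_dict))
    with np.load(path.with_suffix(".npz")) as zf:
        model.load_state_dict({k: zf[k] for k in zf.files})
    return model


# ---------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------

def train(model_cfg: ModelConfig, data, cfg: TrainConfig, *,
          holdout: bool = True, augment_data: bool = False,
          eps: float = 1e-5, verbose: bool = False,
          model: LgmaNet | None = None) -> tuple[RunRecord, LgmaNet]:
    """Train a model and checkpoint the last-epoch weights.

    ``data`` may be a DatasetSpec, a SynthSpec, or a list of SamplePairs.
    Returns the run record and the trained model; weights are also written
    under ``cfg.checkpoint_dir``.
    """
    train_pairs, _ = resolve_data(data, holdout=holdout)
    if model is None:
        model = build_model(model_cfg, seed=cfg.seed)
    model.train()
    opt = nn.Adam(model.parameters(), lr=cfg.lr0)
    shuffle_rng = np.random.default_rng(cfg.seed + 1000)
    aug_rng = np.random.default_rng(cfg.seed + 2000)
    record = RunRecord()
    n = len(train_pairs)
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        opt.lr = lr
        order = shuffle_rng.permutation(n)
        losses = []
        t0 = time.time()
        for start in range(0, n, cfg.batch_size):
            batch = [train_pairs[i] for i in order[start:start + cfg.batch_size]]
            if augment_data:
                batch = [augment(p, aug_rng) for p in batch]
            xb, yb = _stack(batch)
            logits = model(Tensor(xb))
            prob = nn.sigmoid(logits)
            loss = dice_loss(prob, Tensor(yb), eps=eps)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record.epochs.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
        if verbose:
            print(f"epoch {epoch:4d}  loss {np.mean(losses):.4f}  lr {lr:.2e}  "
                  f"({time.time() - t0:.1f}s)", flush=True)
    ckpt = save_checkpoint(model, Path(cfg.checkpoint_dir) / "checkpoint")
    record.checkpoint_path = str(ckpt)
    return record, model


def predict(model: LgmaNet, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
    """Sigmoid probabilities for a (N,3,H,W) stack, in eval mode."""
    model.eval()
    out = []
    for start in range(0, images.shape[0], batch_size):
        logits = model(Tensor(images[start:start + batch_size]))
        out.append(1.0 / (1.0 + np.exp(-logits.data)))
    return np.concatenate(out, axis=0)


def evaluate(model_or_ckpt, data, threshold: float = 0.5,
             batch_size: int = 4) -> MetricsReport:
    """Per-image metrics over the test portion of ``data`` (all pairs when a
    plain list is given)."""
    if isinstance(model_or_ckpt, (str, Path)):
        model = load_checkpoint(model_or_ckpt)
    else:
        model = model_or_ckpt
    _, test_pairs = resolve_data(data)
    x, y = _stack(test_pairs)
    if x.shape[2] % 32 or x.shape[3] % 32:
        raise ValueError(f"evaluation resolution {x.shape[2]}x{x.shape[3]} "
                         f"is not divisible by 32")
    probs = predict(model, x, batch_size)
    ids = [p.stem or str(i) for i, p in enumerate(test_pairs)]
    return MetricsReport.from_pairs(ids, probs, y, threshold)


def ablation_sweep(data, model_cfg: ModelConfig, train_cfg: TrainConfig,
                   out_csv=None, verbose: bool = False) -> dict[str, MetricsReport]:
    """Train and evaluate the four wirings (baseline, +LGIPB, +EMRA, full)
    under identical seeds and an identical data split."""
    from .network import count_parameters
    reports: dict[str, MetricsReport] = {}
    rows = []
    from dataclasses import replace
    for variant in VARIANTS:
        vcfg = make_variant(model_cfg, variant)
        tcfg = replace(train_cfg,
                       checkpoint_dir=str(Path(train_cfg.checkpoint_dir) / variant))
        _, model = train(vcfg, data, tcfg, verbose=verbose)
        rep = evaluate(model, data)
        reports[variant] = rep
        agg = rep.aggregate
        rows.append({"variant": variant,
                     **{k: round(v, 4) for k, v in agg.items()},
                     "params": count_parameters(model).total_params})
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=list(rows[0]))
            wr.writeheader()
            wr.writerows(rows)
    return reports
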