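"""Desk-scale study fixtures.

Two canned experiments exercise the full pipeline end to end at sizes a
single CPU handles in minutes:

* :func:`overfit_demo` — fit the full model to a tiny 8-image synthetic set
  at 96 px until it reproduces its own training masks (a capacity/plumbing
  sanity check: Dice well above 0.9 after 300 optimisation steps).
* :func:`ablation_demo` — train all four wirings (baseline, +LGIPB, +EMRA,
  full) briefly on a 40-image noisy synthetic set under one shared split
  and seed, producing the four-row ablation report.

The fixture sizes (8 / 40 images, 96 px, 300 / 32 steps) and the fixture
training regime (Adam, cosine schedule, lr0 1e-3, small batches) are frozen
study conditions, not tuning knobs.
"""

from __future__ import annotations

from pathlib import Path

from .config import ModelConfig, SynthSpec, TrainConfig
from .metrics import MetricsReport
from .network import LgmaNet
from .train import RunRecord, ablation_sweep, evaluate, train

OVERFIT_STEPS = 300
OVERFIT_BATCH = 2
OVERFIT_PAIRS = 8
FIXTURE_SIZE = 96
FIXTURE_LR = 1e-3


def overfit_spec(seed: int) -> SynthSpec:
    return SynthSpec(n_images=OVERFIT_PAIRS, size=FIXTURE_SIZE, seed=seed)


def overfit_demo(seed: int = 0, steps: int = OVERFIT_STEPS,
                 checkpoint_dir: str | Path = "scratch/overfit",
                 verbose: bool = False) -> tuple[RunRecord, LgmaNet, MetricsReport]:
    """Overfit the full model to its 8-pair fixture and evaluate on the same
    pairs. Returns (run record, model, metrics report)."""
    spec = overfit_spec(seed)
    steps_per_epoch = OVERFIT_PAIRS // OVERFIT_BATCH
    epochs = max(steps // steps_per_epoch, 1)
    tc = TrainConfig(epochs=epochs, batch_size=OVERFIT_BATCH, lr0=FIXTURE_LR,
                     seed=seed, checkpoint_dir=str(checkpoint_dir))
    record, model = train(ModelConfig(), spec, tc, holdout=False, verbose=verbose)
    report = evaluate(model, _all_pairs(spec))
    record.final_metrics = report
    return record, model, report


def _all_pairs(spec: SynthSpec):
    from .data import synth_pairs
    return synth_pairs(spec)


def ablation_spec(seed: int) -> SynthSpec:
    # low contrast + every artifact kind: hard enough that the attention and
    # dense-fusion modules have signal to contribute
    return SynthSpec(n_images=40, size=FIXTURE_SIZE, seed=seed, contrast=0.22,
                     noise_profile=("hair_streaks", "patch_artifacts",
                                    "speckle", "blur_boundary"))


def ablation_demo(seed: int = 0, epochs: int = 6,
                  out_csv: str | Path | None = None,
                  checkpoint_dir: str | Path = "scratch/ablation",
                  verbose: bool = False) -> dict[str, MetricsReport]:
    """Train and evaluate the four ablation wirings on the shared noisy
    fixture (identical split and seed for every variant)."""
    spec = ablation_spec(seed)
    tc = TrainConfig(epochs=epochs, batch_size=4, lr0=FIXTURE_LR, seed=seed,
                     checkpoint_dir=str(checkpoint_dir))
    return ablation_sweep(spec, ModelConfig(), tc, out_csv=out_csv, verbose=verbose)
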