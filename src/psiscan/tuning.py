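"""Three-stage hyperparameter tuning by stratified k-fold cross-validation.

The search runs in three sequential stages, each a full grid over two
hyperparameters with everything else held at the base (or previously
selected) values:

  1. batch size and number of epochs,
  2. number of channels and filter height,
  3. learning rate and dropout probability.

Every combination is scored by the mean held-out-fold accuracy over k = 5
stratified folds; the winner of each stage is carried into the next.  Ties
resolve to the first combination in candidate-list order, so results are
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .metrics import compute_metrics, confusion_from_predictions
from .network import ModelConfig, MultiChannelCNN

__all__ = ["GridSpec", "TuningResult", "TABLE_GRID", "kfold_split", "staged_grid_search"]


@dataclass
class GridSpec:
    """Candidate lists per stage; ``k`` is the fold count."""

    batch_size: list[int]
    max_epochs: list[int]
    n_channels: list[int]
    filter_height: list[int]
    learning_rate: list[float]
    dropout_p: list[float]
    k: int = 5

    def __post_init__(self) -> None:
        for name in ("batch_size", "max_epochs", "n_channels", "filter_height",
                     "learning_rate", "dropout_p"):
            if not getattr(self, name):
                raise ValueError(f"empty candidate list for {name}")
        if self.k < 2:
            raise ValueError("k must be at least 2")

    @property
    def stages(self) -> list[list[str]]:
        return [
            ["batch_size", "max_epochs"],
            ["n_channels", "filter_height"],
            ["learning_rate", "dropout_p"],
        ]

    def total_fits(self) -> int:
        sizes = {name: len(getattr(self, name)) for name in
                 ("batch_size", "max_epochs", "n_channels", "filter_height",
                  "learning_rate", "dropout_p")}
        return self.k * sum(
            int(np.prod([sizes[p] for p in stage])) for stage in self.stages
        )


#: The published search ranges for the staged grid.
TABLE_GRID = GridSpec(
    batch_size=[16, 32, 64, 128],
    max_epochs=[10, 50, 100, 200],
    n_channels=[5, 7, 9, 11],
    filter_height=[3, 5, 7, 9],
    learning_rate=[0.0001, 0.0003, 0.0005, 0.0007, 0.001],
    dropout_p=[0.4, 0.45, 0.5, 0.55, 0.6],
)


@dataclass
class TuningResult:
    selected: ModelConfig
    records: pd.DataFrame  # one row per (stage, combination): params + mean CV accuracy
    stage_logs: list[dict] = field(default_factory=list)
    n_fits: int = 0


def kfold_split(labels: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """Stratified k-fold index partition with a seeded shuffle.

    Returns k disjoint index arrays covering 0..n-1 whose sizes differ by at
    most one and whose class proportions match the whole set.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) < k:
        raise ValueError(f"cannot split {len(labels)} samples into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(labels)), labels)]


def _apply_params(cfg: ModelConfig, params: dict) -> ModelConfig:
    """Override a config with stage candidates. ``filter_height`` sets every
    channel to that height (single-tuned-height convention)."""
    params = dict(params)
    height = params.pop("filter_height", None)
    n_channels = params.pop("n_channels", cfg.n_channels)
    if height is None:
        height = cfg.filter_heights[0]
    return cfg.replace(
        n_channels=n_channels, filter_heights=[height] * n_channels, **params
    )


def _cv_accuracy(cfg: ModelConfig, X: np.ndarray, y: np.ndarray,
                 folds: list[np.ndarray]) -> float:
    """Mean held-out-fold accuracy; each fold's model trains on the other
    folds with the held-out fold serving as the early-stopping monitor."""
    accs = []
    all_idx = np.arange(len(X))
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = MultiChannelCNN(cfg)
        model.fit(X[train_idx], y[train_idx], X[test_idx], y[test_idx])
        _, pred = model.predict(X[test_idx])
        acc = compute_metrics(confusion_from_predictions(y[test_idx], pred)).accuracy
        accs.append(acc)
    return float(np.mean(accs))


def staged_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: GridSpec,
    base_cfg: ModelConfig,
    evaluate: Callable[[ModelConfig, np.ndarray, np.ndarray, list[np.ndarray]], float]
    | None = None,
) -> TuningResult:
    """Run the three-stage grid search on an encoded dataset.

    ``X`` is the (n, rows, cols) encoded tensor (merged-seq during tuning by
    convention), ``y`` the integer labels.  ``evaluate`` may be injected for
    testing; the default is :func:`_cv_accuracy`.  A combination whose
    evaluation raises is logged as failed and excluded from selection.
    """
    y = np.asarray(y, dtype=int)
    folds = kfold_split(y, grid.k, base_cfg.seed)
    evaluate = evaluate or _cv_accuracy
    cfg = base_cfg
    rows: list[dict] = []
    stage_logs: list[dict] = []
    n_fits = 0
    for stage_no, names in enumerate(grid.stages, start=1):
        cand_a, cand_b = (getattr(grid, n) for n in names)
        best_score, best_params = -np.inf, None
        for a in cand_a:
            for b in cand_b:
                params = {names[0]: a, names[1]: b}
                trial_cfg = _apply_params(cfg, params)
                row = {"stage": stage_no, **params}
                try:
                    score = evaluate(trial_cfg, X, y, folds)
                    n_fits += grid.k
                    row["mean_cv_accuracy"] = score
                    row["status"] = "ok"
                    if score > best_score:  # strict: first-in-order tie-break
                        best_score, best_params = score, params
                except Exception as exc:  # noqa: BLE001 — failed combo is data
                    row["mean_cv_accuracy"] = np.nan
                    row["status"] = f"failed: {exc}"
                rows.append(row)
        if best_params is None:
            raise RuntimeError(f"every combination failed in stage {stage_no}")
        cfg = _apply_params(cfg, best_params)
        stage_logs.append(
            {"stage": stage_no, "selected": dict(best_params), "mean_cv_accuracy": best_score}
        )
    return TuningResult(
        selected=cfg, records=pd.DataFrame(rows), stage_logs=stage_logs, n_fits=n_fits
    )
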