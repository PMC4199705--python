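"""Repeated random-partition cross-validation and model comparison.

Predictive ability is measured the way plant-breeding benchmarks report it:
many random 90/10 train/test splits, Pearson correlation between predicted
and observed phenotypes, predictive mean squared error (PMSE), and pairwise
win counts across partitions.  Everything fold-specific — y centring, the
SVD basis, hyperparameter defaults — is recomputed from the training rows
only, so no test information leaks into the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AlignedDataset, MarkerMatrix
from .gibbs import ChainConfig, run_chain, summarize_fit, predict_values
from .models import ModelSpec

__all__ = [
    "CVScheme",
    "CVResult",
    "make_partitions",
    "score_predictions",
    "run_cross_validation",
    "pairwise_win_counts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVScheme:
    """Number of random partitions, held-out fraction, and split seed."""

    n_partitions: int = 50
    test_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie strictly between 0 and 1")
        if self.n_partitions < 1:
            raise ValueError("need at least one partition")


@dataclass
class CVResult:
    """Per-partition scores, per-model means, and pairwise win counts."""

    per_partition: pd.DataFrame   # columns: partition, model, correlation, pmse
    means: pd.DataFrame           # columns: model, mean_correlation, mean_pmse
    win_counts: pd.DataFrame      # columns: model_a, model_b, wins_a, wins_b, ties
    n_skipped: int = 0


def make_partitions(n: int, scheme: CVScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random train/test index splits; test size round(fraction*n), min 1."""
    if n < 2:
        raise ValueError("need at least 2 lines to partition")
    m = max(1, int(round(scheme.test_fraction * n)))
    if m >= n:
        raise ValueError(f"test size {m} leaves no training lines (n = {n})")
    rng = np.random.default_rng(scheme.seed)
    out = []
    for _ in range(scheme.n_partitions):
        perm = rng.permutation(n)
        out.append((np.sort(perm[m:]), np.sort(perm[:m])))
    return out


def score_predictions(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and PMSE; correlation is NaN for constant y_obs."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1 or y_obs.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    pmse = float(np.mean((y_obs - y_pred) ** 2))
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        return float("nan"), pmse
    corr = float(np.corrcoef(y_obs, y_pred)[0, 1])
    return corr, pmse


def run_cross_validation(
    aligned: AlignedDataset,
    specs: list[ModelSpec],
    scheme: CVScheme,
    config: ChainConfig,
) -> CVResult:
    """Fit every model on every partition's training rows and score the rest.

    Chain seeds are derived from (config.seed, partition index, model slot),
    so results are reproducible and independent of which other models run
    alongside.  Degenerate partitions (e.g. a constant training phenotype)
    are skipped with a warning and counted in ``n_skipped``.
    """
    if not specs:
        raise ValueError("need at least one model specification")
    y_raw = aligned.y + aligned.mu
    X = aligned.X.values
    marker_ids = aligned.X.marker_ids
    partitions = make_partitions(aligned.n_lines, scheme)

    # Duplicate model names (e.g. the same spec twice for a self-comparison)
    # get a #k suffix so per-model bookkeeping stays unambiguous.
    labels, seen = [], {}
    for spec in specs:
        seen[spec.model] = seen.get(spec.model, 0) + 1
        labels.append(
            spec.model if seen[spec.model] == 1 else f"{spec.model}#{seen[spec.model]}"
        )

    rows = []
    n_skipped = 0
    for p_idx, (train, test) in enumerate(partitions):
        try:
            folds = []
            for m_idx, spec in enumerate(specs):
                seed = int(
                    np.random.SeedSequence(
                        [config.seed, p_idx, m_idx]
                    ).generate_state(1)[0]
                )
                mu_train = float(np.mean(y_raw[train]))
                train_ids = [aligned.X.line_ids[i] for i in train]
                sub = AlignedDataset(
                    X=MarkerMatrix(X[train], train_ids, list(marker_ids)),
                    y=y_raw[train] - mu_train,
                    mu=mu_train,
                )
                cfg = ChainConfig(
                    n_iter=config.n_iter, burn_in=config.burn_in,
                    thin=config.thin, seed=seed,
                )
                fit = summarize_fit(run_chain(sub, spec, cfg))
                y_hat = predict_values(fit, X[test])
                corr, pmse = score_predictions(y_raw[test], y_hat)
                folds.append(
                    {"partition": p_idx, "model": labels[m_idx],
                     "correlation": corr, "pmse": pmse}
                )
        except ValueError as err:
            logger.warning("partition %d skipped: %s", p_idx, err)
            n_skipped += 1
            continue
        rows.extend(folds)

    per_partition = pd.DataFrame(
        rows, columns=["partition", "model", "correlation", "pmse"]
    )
    # plain arithmetic means of the stored per-partition values
    means = pd.DataFrame(
        [
            {
                "model": name,
                "mean_correlation": float(np.mean(
                    per_partition.loc[per_partition["model"] == name, "correlation"]
                    .to_numpy()
                )),
                "mean_pmse": float(np.mean(
                    per_partition.loc[per_partition["model"] == name, "pmse"]
                    .to_numpy()
                )),
            }
            for name in labels
        ]
    )
    wins = []
    names = labels
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            wa = pairwise_win_counts(per_partition, a, b)
            wb = pairwise_win_counts(per_partition, b, a)
            total = per_partition[per_partition["model"] == a].shape[0]
            wins.append(
                {"model_a": a, "model_b": b, "wins_a": wa, "wins_b": wb,
                 "ties": total - wa - wb}
            )
    win_counts = pd.DataFrame(
        wins, columns=["model_a", "model_b", "wins_a", "wins_b", "ties"]
    )
    return CVResult(per_partition, means, win_counts, n_skipped)


def pairwise_win_counts(
    per_partition: pd.DataFrame, model_a: str, model_b: str
) -> int:
    """Partitions on which model_a's correlation strictly exceeds model_b's."""
    a = per_partition[per_partition["model"] == model_a].set_index("partition")
    b = per_partition[per_partition["model"] == model_b].set_index("partition")
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("models were not scored on identical partitions")
    diff = a["correlation"] - b["correlation"].reindex(a.index)
    return int((diff > 0).sum())
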