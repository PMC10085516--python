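"""Coefficient training: labeling, logistic fitting, window grid search and
tissue-aware cross-validation.

Candidate target regions are labeled positive when they overlap gold-standard
peaks on the target genome and negative otherwise.  A logistic regression of
label on the two similarity features is fitted by iteratively reweighted
least squares (optionally ridge-penalized on the slopes), and candidate
generation is repeated over a grid of extension window sizes; the window
maximizing AUROC (AUPR breaking ties) is selected.  Leave-one-dataset-out
cross-validation excludes every dataset sharing the held-out dataset's
tissue from the feature space of that fold and averages the per-fold
coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import average_precision_score, roc_auc_score

from .candidates import (
    DEFAULT_GAP_THRESHOLD,
    DEFAULT_RESOLUTION,
    CandidateTarget,
    generate_candidates,
)
from .chain import ChainIndex
from .features import MatchedFeatureConfig, MotifScanner
from .intervals import GenomicInterval, PeakSet
from .scoring import LogisticParams, score_candidates

__all__ = [
    "LabeledCandidate",
    "TrainingDataset",
    "TrainingReport",
    "DEFAULT_WINDOW_GRID",
    "window_grid",
    "label_candidates",
    "fit_logistic",
    "auroc",
    "aupr",
    "window_grid_search",
    "cross_validate",
]

logger = logging.getLogger(__name__)


def window_grid(
    stop: int = 5000, step: int = 400, flush: bool = False
) -> tuple[int, ...]:
    """Window sizes 0, step, 2*step, ... below ``stop``; ``flush`` appends
    ``stop`` itself when the stepped grid does not land on it."""
    grid = list(range(0, stop + 1, step))
    if flush and grid[-1] != stop:
        grid.append(stop)
    return tuple(grid)


#: 13 windows, 0 to 4800 by 400 bases.
DEFAULT_WINDOW_GRID = window_grid(5000, 400, flush=False)


@dataclass(frozen=True)
class LabeledCandidate:
    E: float
    S: float
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class TrainingDataset:
    """One matched dataset pair with a tissue tag, used both as a feature
    pair and (when held out) as the source of queries and gold labels."""

    name: str
    tissue: str
    query_peaks: PeakSet
    target_peaks: PeakSet
    weight: float = 1.0


@dataclass
class TrainingReport:
    """Per-window results plus the selected window and final coefficients."""

    table: pd.DataFrame
    selected_window: int | None
    params: LogisticParams | None
    fold_params: list[LogisticParams] = field(default_factory=list)
    fold_windows: list[int] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "selected_window": self.selected_window,
            "params": None
            if self.params is None
            else [self.params.beta0, self.params.beta1, self.params.beta2],
            "folds": [
                {"window": w, "params": [p.beta0, p.beta1, p.beta2]}
                for w, p in zip(self.fold_windows, self.fold_params)
            ],
            "table": self.table.to_dict(orient="records"),
        }


def label_candidates(
    cands: Sequence[CandidateTarget], gold: PeakSet
) -> list[LabeledCandidate]:
    """Label 1 iff the candidate target overlaps a gold peak by >= 1 base;
    similarities are carried through unchanged."""
    out = []
    for cand in cands:
        if cand.epi_similarity is None or cand.seq_similarity is None:
            raise ValueError("candidates must be scored before labeling")
        out.append(
            LabeledCandidate(
                E=cand.epi_similarity,
                S=cand.seq_similarity,
                label=1 if gold.overlaps(cand.target) else 0,
            )
        )
    return out


class SeparationError(RuntimeError):
    """Perfectly separable data with no ridge penalty: the MLE diverges."""


def fit_logistic(
    data: Sequence[LabeledCandidate],
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticParams:
    """Fit label ~ beta0 + beta1*E + beta2*S by IRLS.

    ``ridge`` penalizes the two slopes (never the intercept); the default
    1e-6 only guards numerical rank.  Convergence is declared when the
    largest coefficient change drops below ``tol``; complete separation at
    ridge 0 raises :class:`SeparationError` advising a positive ridge.
    """
    if not data:
        raise ValueError("no training data")
    X = np.column_stack(
        [
            np.ones(len(data)),
            np.array([d.E for d in data]),
            np.array([d.S for d in data]),
        ]
    )
    y = np.array([d.label for d in data], dtype=float)
    if ridge == 0.0 and (y.min() == y.max()):
        raise ValueError("need both classes when ridge is 0")
    penalty = np.diag([0.0, ridge, ridge])
    beta = np.zeros(3)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        # one Newton step on the penalized log-likelihood
        gradient = X.T @ (y - mu) - penalty @ beta
        hessian = X.T @ (X * w[:, None]) + penalty
        try:
            step = np.linalg.solve(hessian, gradient)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix; refit with ridge > 0"
            )
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        if ridge == 0.0:
            raise SeparationError(
                "IRLS did not converge (likely complete separation); "
                "refit with ridge > 0"
            )
    if ridge == 0.0 and np.max(np.abs(beta)) > 30.0:
        raise SeparationError(
            "diverging coefficients indicate complete separation; "
            "refit with ridge > 0"
        )
    return LogisticParams(*beta)


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative label")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals the Mann-Whitney statistic
    P(score+ > score-) + 0.5 * P(tie)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve as the step integral of
    precision over recall at every distinct threshold."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def window_grid_search(
    queries: Sequence[GenomicInterval],
    index: ChainIndex,
    config: MatchedFeatureConfig,
    gold: PeakSet,
    query_genome: Mapping[str, object],
    target_genome: Mapping[str, object],
    grid: Sequence[int] = DEFAULT_WINDOW_GRID,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    resolution: int = DEFAULT_RESOLUTION,
    ridge: float = 1e-6,
    scanner: MotifScanner | None = None,
) -> TrainingReport:
    """Candidate generation, scoring, labeling and fitting per window size.

    The selected window maximizes AUROC with AUPR as tie-breaker; windows
    yielding no candidates or single-class labels are recorded with missing
    metrics rather than failing.  Fitted probabilities (equivalently the
    monotone linear predictor) are the scores being evaluated.
    """
    if not grid:
        raise ValueError("window grid must be non-empty")
    if scanner is None:
        scanner = config.scanner()
    # placeholder coefficients; only E,S feed the fit, so any params work here
    neutral = LogisticParams(0.0, 1.0, 1.0)
    rows = []
    fitted: dict[int, LogisticParams] = {}
    for window in grid:
        labeled: list[LabeledCandidate] = []
        for q in queries:
            cands = generate_candidates(
                q, index, window, gap_threshold, resolution
            )
            if not cands:
                continue
            scored = score_candidates(
                cands, config, query_genome, target_genome, neutral, scanner
            )
            labeled.extend(label_candidates(scored, gold))
        n_pos = sum(d.label for d in labeled)
        row = {
            "window": window,
            "n_candidates": len(labeled),
            "n_positive": n_pos,
            "beta0": np.nan,
            "beta1": np.nan,
            "beta2": np.nan,
            "auroc": np.nan,
            "aupr": np.nan,
        }
        if labeled and 0 < n_pos < len(labeled):
            params = fit_logistic(labeled, ridge=ridge)
            scores = [
                params.beta0 + params.beta1 * d.E + params.beta2 * d.S
                for d in labeled
            ]
            y = [d.label for d in labeled]
            row.update(
                beta0=params.beta0,
                beta1=params.beta1,
                beta2=params.beta2,
                auroc=auroc(scores, y),
                aupr=aupr(scores, y),
            )
            fitted[window] = params
        rows.append(row)
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["auroc"])
    if valid.empty:
        return TrainingReport(table=table, selected_window=None, params=None)
    best = valid.sort_values(
        ["auroc", "aupr", "window"], ascending=[False, False, True]
    ).iloc[0]
    selected = int(best["window"])
    return TrainingReport(
        table=table, selected_window=selected, params=fitted[selected]
    )


def cross_validate(
    datasets: Sequence[TrainingDataset],
    index: ChainIndex,
    motifs,
    query_genome: Mapping[str, object],
    target_genome: Mapping[str, object],
    grid: Sequence[int] = DEFAULT_WINDOW_GRID,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    resolution: int = DEFAULT_RESOLUTION,
    flank: int = 0,
    p_cutoff: float = 5e-5,
    ridge: float = 1e-6,
) -> TrainingReport:
    """Leave-one-dataset-out cross-validation with tissue exclusion.

    Each fold holds out one dataset: its query peaks become the queries, its
    target peaks the gold standard, and every dataset sharing its tissue tag
    is excluded from the fold's epigenomic feature space.  Final
    coefficients are the arithmetic mean across folds (the per-fold optima
    vary more than the window does, hence averaging); folds whose labels
    collapse to a single class are skipped with a warning.
    """
    tissues = {d.tissue for d in datasets}
    if len(tissues) < 2:
        raise ValueError("cross-validation requires >= 2 tissues")
    from .features import FeaturePair  # local import to avoid cycle noise

    scanner = MotifScanner(motifs, p_cutoff) if motifs else MotifScanner([], p_cutoff)
    fold_params: list[LogisticParams] = []
    fold_windows: list[int] = []
    tables = []
    for held_out in datasets:
        pairs = [
            FeaturePair(d.query_peaks, d.target_peaks, d.name, d.weight)
            for d in datasets
            if d.tissue != held_out.tissue
        ]
        config = MatchedFeatureConfig(
            pairs=pairs, motifs=list(motifs), flank=flank, p_cutoff=p_cutoff
        )
        report = window_grid_search(
            queries=list(held_out.query_peaks),
            index=index,
            config=config,
            gold=held_out.target_peaks,
            query_genome=query_genome,
            target_genome=target_genome,
            grid=grid,
            gap_threshold=gap_threshold,
            resolution=resolution,
            ridge=ridge,
            scanner=scanner,
        )
        fold_table = report.table.assign(fold=held_out.name)
        tables.append(fold_table)
        if report.params is None:
            logger.warning(
                "fold %s skipped: no window produced two-class labels",
                held_out.name,
            )
            continue
        fold_params.append(report.params)
        fold_windows.append(report.selected_window)
    table = pd.concat(tables, ignore_index=True)
    if not fold_params:
        return TrainingReport(table=table, selected_window=None, params=None)
    mean = np.mean([p.as_array() for p in fold_params], axis=0)
    selected = int(np.median(fold_windows))
    return TrainingReport(
        table=table,
        selected_window=selected,
        params=LogisticParams(*mean),
        fold_params=fold_params,
        fold_windows=fold_windows,
    )
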