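"""Statistical utilities: rank tests, test-time bootstrapping, diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

logger = logging.getLogger(__name__)


def mann_whitney_u(pop_a: Sequence[float], pop_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with tie correction.

    Exact null distribution for small samples (both n <= 8, no ties),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(pop_a, dtype=float)
    b = np.asarray(pop_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both populations must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def classification_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> dict:
    """AUROC (rank-based), accuracy, F1, MCC, precision and recall."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("labels contain a single class")
    pred = (scores >= threshold).astype(int)
    return {
        "auroc": float(skm.roc_auc_score(labels, scores)),
        "accuracy": float(skm.accuracy_score(labels, pred)),
        "f1": float(skm.f1_score(labels, pred, zero_division=0)),
        "mcc": float(skm.matthews_corrcoef(labels, pred)),
        "precision": float(skm.precision_score(labels, pred, zero_division=0)),
        "recall": float(skm.recall_score(labels, pred, zero_division=0)),
    }


@dataclass
class MetricDistribution:
    """One metric's point estimate plus bootstrap replicates."""

    name: str
    point: float
    replicates: np.ndarray
    seed: int

    @property
    def reps(self) -> int:
        return len(self.replicates)

    def summary(self) -> dict:
        return {
            "metric": self.name,
            "point": self.point,
            "mean": float(self.replicates.mean()),
            "std": float(self.replicates.std(ddof=1)) if self.reps > 1 else 0.0,
            "q025": float(np.quantile(self.replicates, 0.025)),
            "q975": float(np.quantile(self.replicates, 0.975)),
            "reps": self.reps,
        }


def bootstrap_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    reps: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> list[MetricDistribution]:
    """Test-time bootstrap: resample (score, label) pairs with replacement
    to full test length, `reps` times; degenerate single-class resamples
    are redrawn (keeping `reps` fixed) and the redraw count logged."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    point = classification_metrics(scores, labels, threshold)
    rng = np.random.default_rng(seed)
    n = len(scores)
    replicates: dict[str, list[float]] = {k: [] for k in point}
    redraws = 0
    for _ in range(reps):
        while True:
            idx = rng.integers(n, size=n)
            if len(set(labels[idx].tolist())) > 1:
                break
            redraws += 1
        rep = classification_metrics(scores[idx], labels[idx], threshold)
        for k, v in rep.items():
            replicates[k].append(v)
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    return [
        MetricDistribution(
            name=k, point=point[k], replicates=np.asarray(v), seed=seed
        )
        for k, v in replicates.items()
    ]


def carbon_dependence(
    scores_by_molecule: dict[str, float], smiles_by_molecule: dict[str, str]
) -> dict:
    """Group robustness scores by heavy-carbon count.

    Returns per-count median/IQR and the Spearman rank correlation between
    carbon count and score (the carbon-dependence diagnostic); correlation
    is flagged undefined for a single group or constant scores.
    """
    from rdkit import Chem

    rows = []
    for mol_id, score in scores_by_molecule.items():
        smiles = smiles_by_molecule[mol_id]
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        n_carbon = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
        rows.append({"molecule_id": mol_id, "carbons": n_carbon, "score": score})
    frame = pd.DataFrame(rows)
    per_group = (
        frame.groupby("carbons")["score"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n="count",
        )
        .reset_index()
    )
    correlation: float | None
    if frame["carbons"].nunique() < 2:
        correlation = None  # a single bucket: dependence undefined
    elif frame["score"].nunique() < 2:
        correlation = 0.0  # constant scores show no dependence
    else:
        correlation = float(
            stats.spearmanr(frame["carbons"], frame["score"]).statistic
        )
    return {
        "per_carbon": per_group,
        "spearman_rho": correlation,
        "undefined": correlation is None,
    }
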