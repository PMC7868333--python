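"""Cohort-level evaluation of simulated adaptive tests.

Summaries mirror the standard reporting for variable-length CAT validation
studies: items administered (mean/SD), mean trait SE, marginal reliability
(the average of per-person reliabilities 1 - 1/I(theta_i)), agreement with
full-pool scores, criterion-related validity (Pearson r), and ROC-based
screening utility (AUC, sensitivity/specificity at the Youden-optimal
operating point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .irt_models import ItemBank

__all__ = [
    "SimulationSummary",
    "ROCResult",
    "summarize_cohort",
    "reliability_curve",
    "criterion_validity",
    "roc_analysis",
]


@dataclass(frozen=True)
class SimulationSummary:
    """The five cohort statistics reported per stopping rule."""

    rule: str
    mean_items: float
    sd_items: float
    mean_se: float
    marginal_reliability: float
    correlation_with_full: float
    n_zero_information: int = 0


@dataclass(frozen=True)
class ROCResult:
    """ROC screening summary at the Youden-optimal cutoff."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    auc_ci: tuple | None = None


def summarize_cohort(records, full_pool_thetas) -> SimulationSummary:
    """Summarize a cohort of :class:`~catdev.cat_engine.CATRecord` traces.

    ``full_pool_thetas`` maps person id -> EAP score on the complete pool (or
    is a sequence aligned with ``records``). Marginal reliability averages
    r(theta_i) = 1 - 1/I(theta_i) over persons; zero-information persons are
    excluded from that average and counted.
    """
    if hasattr(full_pool_thetas, "get"):
        full = np.array([float(full_pool_thetas[r.person_id]) for r in records])
    else:
        full = np.asarray(full_pool_thetas, dtype=float)
        if full.shape[0] != len(records):
            raise ValueError("full-pool thetas must align with records")
    n_items = np.array([len(r.administered) for r in records], dtype=float)
    ses = np.array([r.final.se for r in records])
    infos = np.array([r.final.information for r in records])
    thetas = np.array([r.final.theta for r in records])
    pos = infos > 0
    rel = 1.0 - 1.0 / infos[pos]
    corr = float(np.corrcoef(thetas, full)[0, 1])
    rules = {r.stop_reason for r in records}
    label = "se" if "se_met" in rules else "none"
    return SimulationSummary(
        rule=label,
        mean_items=float(n_items.mean()),
        sd_items=float(n_items.std(ddof=0)),
        mean_se=float(ses[np.isfinite(ses)].mean()),
        marginal_reliability=float(rel.mean()) if pos.any() else float("nan"),
        correlation_with_full=corr,
        n_zero_information=int((~pos).sum()),
    )


def reliability_curve(theta_grid, bank: ItemBank, subset=None) -> np.ndarray:
    """Reliability r(theta) = 1 - 1/I(theta) of an item set along a theta grid.

    Grid points with zero information yield NaN (reliability undefined).
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    sub = bank if subset is None else bank.subset(list(subset))
    info = sub.information_matrix(theta_grid).sum(axis=1)
    out = np.full_like(theta_grid, np.nan)
    pos = info > 0
    out[pos] = 1.0 - 1.0 / info[pos]
    return out


def criterion_validity(theta_hats, criterion_scores) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) between trait estimates and an
    external criterion score."""
    x = np.asarray(theta_hats, dtype=float)
    y = np.asarray(criterion_scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in scores")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction: mean rank of cases."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_analysis(scores, labels, n_boot: int = 0, seed: int = 0,
                 cutoff: float | None = None) -> ROCResult:
    """ROC analysis of trait scores against binary diagnosis labels.

    The AUC is the rank (Mann-Whitney) statistic with tie correction. The
    operating point maximizes the Youden index J = sensitivity + specificity
    - 1 over the ROC curve, unless a fixed ``cutoff`` is supplied. With
    ``n_boot > 0`` a seeded bootstrap percentile CI for the AUC is attached.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    auc = _rank_auc(scores, labels)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    if cutoff is None:
        best = int(np.argmax(tpr - fpr))
        chosen = float(thresholds[best])
        se_, sp_ = float(tpr[best]), float(1.0 - fpr[best])
    else:
        chosen = float(cutoff)
        pred = scores >= chosen
        se_ = float(pred[labels == 1].mean())
        sp_ = float((~pred)[labels == 0].mean())
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = scores.size
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(n, size=n)
            lb = labels[idx]
            if lb.min() == lb.max():
                continue
            vals.append(roc_auc_score(lb, scores[idx]))
        ci = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return ROCResult(auc=auc, cutoff=chosen, sensitivity=se_, specificity=sp_,
                     youden=se_ + sp_ - 1.0, fpr=fpr, tpr=tpr, auc_ci=ci)
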