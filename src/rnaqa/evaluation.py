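"""Scoring-assessment metrics for structure quality estimators.

Global metrics pool every (target, model) record; per-target metrics are
computed within each target and averaged unweighted across targets.
Covered: Pearson/Spearman/Kendall correlations, the mean absolute
difference ("diff"), top-1 loss (quality gap between the model a scorer
ranks first and the truly best model), ROC-AUC for separating good from
bad models at an lDDT threshold of 0.75, a TM-score-style length
normalisation of RMSD, min-max recalibration of energy-like scores, and a
composite quality score Q_c averaging five of these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_AUC_THRESHOLD = 0.75


class DegenerateMetricError(ValueError):
    """Inputs leave the metric undefined (constant scores, one class...)."""


@dataclass(frozen=True)
class ScoreRecord:
    target_id: str
    model_id: str
    predicted: float
    truth_lddt: float
    truth_rmsd: float | None = None


@dataclass(frozen=True)
class MetricsReport:
    r_g: float
    rho_g: float
    tau_g: float
    diff: float
    auc: float
    r_a: float
    rho_a: float
    tau_a: float
    loss: float
    q_c: float
    skipped_targets: int = 0


def as_records(rows) -> list[ScoreRecord]:
    return [r if isinstance(r, ScoreRecord) else
            ScoreRecord(r["target_id"], r["model_id"], float(r["predicted"]),
                        float(r["truth_lddt"]), r.get("truth_rmsd"))
            for r in rows]


def _corr(kind: str, x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateMetricError("undefined correlation: constant input")
    if kind == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if kind == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if kind == "kendall":
        return float(stats.kendalltau(x, y).statistic)
    raise ValueError(f"unknown correlation kind {kind!r}")


def _by_target(records: list[ScoreRecord]) -> dict[str, list[ScoreRecord]]:
    out: dict[str, list[ScoreRecord]] = {}
    for r in records:
        out.setdefault(r.target_id, []).append(r)
    return out


def correlations(records, level: str = "global", kind: str = "pearson",
                 truth: str = "truth_lddt") -> float | tuple[float, int]:
    """Correlation between predicted scores and the ground truth.

    ``level="global"`` pools all records into one coefficient;
    ``level="per_target"`` averages per-target coefficients unweighted and
    returns ``(mean, n_skipped)`` where targets with zero variance in either
    variable are skipped.
    """
    records = as_records(records)
    get = lambda r: getattr(r, truth)
    if level == "global":
        x = np.array([r.predicted for r in records])
        y = np.array([get(r) for r in records])
        return _corr(kind, x, y)
    if level != "per_target":
        raise ValueError(f"unknown level {level!r}")
    vals, skipped = [], 0
    for recs in _by_target(records).values():
        x = np.array([r.predicted for r in recs])
        y = np.array([get(r) for r in recs])
        try:
            vals.append(_corr(kind, x, y))
        except DegenerateMetricError:
            skipped += 1
    if not vals:
        raise DegenerateMetricError("undefined correlation: every target degenerate")
    return float(np.mean(vals)), skipped


def diff_metric(records, truth: str = "truth_lddt") -> float:
    """Mean absolute difference between predicted and true scores, pooled."""
    records = as_records(records)
    if not records:
        raise ValueError("no records")
    return float(np.mean([abs(r.predicted - getattr(r, truth)) for r in records]))


def top1_loss(records, truth: str = "truth_lddt") -> float:
    """Per target: |truth(top-ranked model) - best truth|; mean over targets.
    Ties in predicted score break deterministically by model id."""
    records = as_records(records)
    losses = []
    for recs in _by_target(records).values():
        top = max(recs, key=lambda r: (r.predicted, r.model_id))
        best = max(getattr(r, truth) for r in recs)
        losses.append(abs(best - getattr(top, truth)))
    return float(np.mean(losses))


def roc_auc(records, threshold: float = DEFAULT_AUC_THRESHOLD) -> float:
    """AUC of the predicted score separating good (truth lDDT >= threshold)
    from bad models: the Mann-Whitney U statistic over n+ * n-, ties 1/2."""
    records = as_records(records)
    labels = np.array([r.truth_lddt >= threshold for r in records])
    scores = np.array([r.predicted for r in records])
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateMetricError("degenerate ROC: single class")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def d0_rna(L: int) -> float:
    """Length-dependent distance scale: max(0.6 sqrt(L - 0.5) - 2.5, 1.0)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return max(0.6 * np.sqrt(L - 0.5) - 2.5, 1.0)


def normalize_rmsd(rmsd: float, L: int, d0=d0_rna) -> float:
    """Map an RMSD (A) into (0, 1], higher = better: 1 / (1 + (rmsd/d0(L))^2)."""
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    return 1.0 / (1.0 + (rmsd / d0(L)) ** 2)


def minmax_recalibrate(energies) -> np.ndarray:
    """Map energy-like scores (lower = better) to [0, 1] with higher = better:
    1 - (e - min) / (max - min), pooled over the evaluated set."""
    e = np.asarray(energies, dtype=float)
    if e.size < 2 or np.ptp(e) == 0:
        raise DegenerateMetricError("degenerate normalization: constant energies")
    return 1.0 - (e - e.min()) / (e.max() - e.min())


def composite_qc(r_g: float, diff: float, r_a: float, loss: float, auc: float) -> float:
    """Composite quality score: average of r_g, (1 - diff), r_a, (1 - loss)
    and AUC. Loss-like terms are complemented so that higher is better."""
    for name, v in (("r_g", r_g), ("diff", diff), ("r_a", r_a),
                    ("loss", loss), ("auc", auc)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing component: {name}")
    return (r_g + (1.0 - diff) + r_a + (1.0 - loss) + auc) / 5.0


def full_report(records, threshold: float = DEFAULT_AUC_THRESHOLD) -> MetricsReport:
    """Compute the complete metric battery on pooled records."""
    records = as_records(records)
    r_g = correlations(records, "global", "pearson")
    rho_g = correlations(records, "global", "spearman")
    tau_g = correlations(records, "global", "kendall")
    r_a, sk1 = correlations(records, "per_target", "pearson")
    rho_a, sk2 = correlations(records, "per_target", "spearman")
    tau_a, sk3 = correlations(records, "per_target", "kendall")
    d = diff_metric(records)
    l1 = top1_loss(records)
    auc = roc_auc(records, threshold)
    qc = composite_qc(r_g, d, r_a, l1, auc)
    return MetricsReport(r_g=r_g, rho_g=rho_g, tau_g=tau_g, diff=d, auc=auc,
                         r_a=r_a, rho_a=rho_a, tau_a=tau_a, loss=l1, q_c=qc,
                         skipped_targets=max(sk1, sk2, sk3))
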