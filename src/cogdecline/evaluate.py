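"""Model evaluation: ROC/AUC, confusion metrics, repeated-subsampling CV,
and clinical-characteristics cohort reports.

AUC ties are weighted 1/2 (Mann-Whitney convention) — material here because
a handful of binary features yields heavily tied posteriors.  Cross-
validation draws simple (unstratified) random 80/20 splits; test splits
missing an outcome class are redrawn and the redraw count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EvaluationError
from .lrstats import group_compare
from .model import PrognosticModel, estimate_priors, _refit_lrs

__all__ = [
    "EvaluationResult",
    "roc_and_auc",
    "confusion_metrics",
    "repeated_subsampling_cv",
    "cohort_report",
]


@dataclass
class EvaluationResult:
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    accuracy: float = float("nan")
    auc: float = float("nan")
    roc: np.ndarray | None = None  # (1-specificity, sensitivity) points
    cv_mean_auc: float = float("nan")
    cv_sd_auc: float = float("nan")
    cv_aucs: np.ndarray | None = field(default=None, repr=False)
    n_repetitions: int = 0
    n_redraws: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "cv_mean_auc": self.cv_mean_auc,
            "cv_sd_auc": self.cv_sd_auc,
            "n_repetitions": self.n_repetitions,
            "n_redraws": self.n_redraws,
            "seed": self.seed,
        }


def roc_and_auc(posteriors, labels):
    """ROC curve over all distinct score cutoffs and its trapezoidal AUC.

    The trapezoidal AUC over the full cutoff sweep equals the tie-corrected
    Mann-Whitney statistic P(score_case > score_control) + P(=)/2.
    """
    scores = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if scores.shape != y.shape:
        raise EvaluationError("scores and labels differ in length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both outcome classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def confusion_metrics(predicted, labels):
    """Sensitivity, specificity and accuracy of boolean predictions."""
    pred = np.asarray(predicted, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if pred.shape != y.shape or pred.size == 0:
        raise EvaluationError("predictions and labels must align and be nonempty")
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both outcome classes must be present")
    return tp / n1, tn / n0, (tp + tn) / y.size


def evaluate_model(model: PrognosticModel, df: pd.DataFrame,
                   label_col: str = "decline") -> EvaluationResult:
    """Single-cohort evaluation at the model's decision cutoff."""
    y = df[label_col].astype(bool).to_numpy()
    p = model.predict_proba(df)
    roc, auc = roc_and_auc(p, y)
    sens, spec, acc = confusion_metrics(p >= model.decision_cutoff, y)
    return EvaluationResult(sensitivity=sens, specificity=spec, accuracy=acc,
                            auc=auc, roc=roc)


def repeated_subsampling_cv(
    df: pd.DataFrame,
    model_template: PrognosticModel,
    train_fraction: float = 0.8,
    reps: int = 300,
    seed: int | None = None,
    label_col: str = "decline",
    max_redraws_per_rep: int = 1000,
) -> EvaluationResult:
    """Repeated random subsampling cross-validation of the fitting pipeline.

    Per repetition a uniform random split assigns floor(train_fraction * n)
    subjects to training (remainder to test); age-bracket priors and the
    per-feature LRs of the template's fixed feature set are refit on the
    training split and the AUC of the refit model is measured on the test
    split.  Splits whose test half lacks an outcome class are redrawn
    (counted in ``n_redraws``).  Fully reproducible from ``seed``.
    """
    if reps < 1:
        raise EvaluationError("reps must be >= 1")
    y = df[label_col].astype(bool).to_numpy()
    n = len(df)
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1 or n - n_train < 2 or y.sum() == 0 or (~y).sum() == 0:
        raise EvaluationError("cohort too small to form a two-class test split")
    rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    redraws = 0
    for r in range(reps):
        for _ in range(max_redraws_per_rep):
            perm = rng.permutation(n)
            test_idx = perm[n_train:]
            if y[test_idx].any() and not y[test_idx].all():
                break
            redraws += 1
        else:
            raise EvaluationError(
                "could not draw a two-class test split; cohort too imbalanced"
            )
        train = df.iloc[perm[:n_train]]
        test = df.iloc[test_idx]
        refit = PrognosticModel(
            priors=estimate_priors(
                train,
                brackets=model_template.priors.brackets,
                label_col=label_col,
            ),
            features=model_template.features,
            decision_cutoff=model_template.decision_cutoff,
        )
        refit = _refit_lrs(refit, train, label_col)
        _, aucs[r] = roc_and_auc(refit.predict_proba(test),
                                 test[label_col].astype(bool).to_numpy())
    return EvaluationResult(
        cv_mean_auc=float(aucs.mean()),
        cv_sd_auc=float(aucs.std(ddof=1)) if reps > 1 else 0.0,
        cv_aucs=aucs,
        n_repetitions=reps,
        n_redraws=redraws,
        seed=seed,
    )


def cohort_report(
    df: pd.DataFrame,
    variables: dict | None = None,
    label_col: str = "decline",
) -> pd.DataFrame:
    """Clinical-characteristics table by outcome group.

    ``variables`` maps column -> kind (``"numeric"``, ``"discrete"`` or
    ``"categorical"``); unlisted columns are skipped.  Numeric variables are
    summarized as ``mean ± sd (min–max)`` per group with the normality-gated
    two-group test; categorical ones as ``k/n (pct%)`` with Fisher's exact
    test.  Missing values are dropped per comparison.
    """
    if variables is None:
        variables = {
            c: "numeric"
            for c in df.select_dtypes("number").columns
            if c not in (label_col,)
        }
    y = df[label_col].astype(bool)
    groups = {"no_decline": df[~y], "decline": df[y]}
    rows = []
    for col, kind in variables.items():
        row = {"variable": col, "kind": kind}
        if kind == "categorical":
            for gname, g in groups.items():
                vals = g[col].dropna().astype(bool)
                k, m = int(vals.sum()), len(vals)
                pct = 100.0 * k / m if m else float("nan")
                row[gname] = f"{k}/{m} ({pct:.2f}%)"
            table = [
                [int(g[col].dropna().astype(bool).sum()),
                 int((~g[col].dropna().astype(bool)).sum())]
                for g in groups.values()
            ]
            from .lrstats import fisher_exact

            try:
                row["test"], row["p"] = "fisher_exact", fisher_exact(table)
            except Exception:
                row["test"], row["p"] = "not_applicable", float("nan")
        else:
            for gname, g in groups.items():
                vals = pd.to_numeric(g[col], errors="coerce").dropna()
                if vals.empty:
                    row[gname] = "–"
                    continue
                row[gname] = (
                    f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f} "
                    f"({vals.min():.2f}–{vals.max():.2f})"
                )
            vals = pd.to_numeric(df[col], errors="coerce")
            try:
                cmp = group_compare(vals, y.to_numpy(),
                                    discrete=(kind == "discrete"))
                row["test"], row["p"] = cmp.test, cmp.p
            except Exception:
                row["test"], row["p"] = "not_applicable", float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
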