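"""Per-feature scoring ANNs: continuous, range-bounded slide scores.

Each feature's slide-feature vectors (length 2K+1) are regressed onto the
discrete pathologist scores by a small feedforward network whose output
unit passes through a scaled logistic, so predictions stay inside the
pathologist range [0, S] while remaining continuous.  Training minimizes
mean squared error; evaluation uses out-of-fold predictions from
score-stratified 4-fold cross-validation over slides (never tiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .features import SLIDE_SCORE_MAX
from .nn.mlp import BoundedRegressionMLP, bounded_activation  # noqa: F401  (re-exported)

NAS_COMPONENTS = ("steatosis", "inflammation", "ballooning")


@dataclass
class ScoringResult:
    """Cross-validated scoring of one feature over a cohort.

    ``models`` holds one small seed-ensemble per fold; predictions average
    over every member of every fold.
    """

    feature: str
    s_max: float
    models: list[list[BoundedRegressionMLP]]
    records: pd.DataFrame  # slide_id, feature, truth, ai_score, fold
    curves: pd.DataFrame  # fold, member, epoch, mse

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Ensemble prediction for slides outside the training cohort."""
        x = np.atleast_2d(x)
        return np.mean([m.predict(x) for fold in self.models for m in fold], axis=0)


def train_scoring_ann(
    features: np.ndarray,
    truth: np.ndarray,
    feature: str,
    slide_ids=None,
    folds: int = 4,
    hidden: tuple[int, int] = (16, 8),
    epochs: int = 600,
    lr: float = 0.01,
    ensemble: int = 3,
    seed: int = 0,
) -> ScoringResult:
    """Cross-validated MSE training of the scoring ANN for one feature.

    Slides with missing truth (NaN) are excluded.  Folds partition slides,
    stratified by truth score (best effort: plain shuffled folds when some
    score level has fewer members than folds); each slide receives exactly
    one out-of-fold prediction, averaged over a small ensemble of
    differently initialized networks per fold (initialization variance is
    substantial with a few dozen training slides).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(truth, dtype=float)
    if slide_ids is None:
        slide_ids = np.array([f"slide_{i}" for i in range(len(y))])
    slide_ids = np.asarray(slide_ids)
    keep = ~np.isnan(y) & ~np.isnan(x).any(axis=1)
    if keep.sum() < keep.size:
        warnings.warn(f"{feature}: excluding {int((~keep).sum())} slides with missing truth or features", stacklevel=2)
    x, y, slide_ids = x[keep], y[keep], slide_ids[keep]
    if len(y) < folds:
        raise ValueError(f"need at least {folds} scored slides, got {len(y)}")
    s_max = float(SLIDE_SCORE_MAX[feature])

    y_int = np.rint(y).astype(int)
    counts = np.bincount(y_int, minlength=1)
    if counts[counts > 0].min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(x, y_int)
    else:
        warnings.warn(
            f"{feature}: some score level has fewer than {folds} slides; falling back to unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(x)

    models: list[list[BoundedRegressionMLP]] = []
    rec_rows = []
    curve_rows = []
    for fold, (tr, te) in enumerate(split_iter):
        fold_models = []
        fold_preds = []
        for member in range(max(ensemble, 1)):
            model = BoundedRegressionMLP(x.shape[1], s_max, hidden=hidden, seed=seed + 17 * fold + member)
            curve = model.fit(x[tr], y[tr], epochs=epochs, lr=lr)
            fold_models.append(model)
            fold_preds.append(model.predict(x[te]))
            curve_rows.extend(
                {"fold": fold, "member": member, "epoch": e, "mse": m} for e, m in enumerate(curve)
            )
        preds = np.mean(fold_preds, axis=0)
        models.append(fold_models)
        rec_rows.extend(
            {
                "slide_id": slide_ids[i],
                "feature": feature,
                "truth": y[i],
                "ai_score": float(p),
                "fold": fold,
            }
            for i, p in zip(te, preds)
        )
    records = pd.DataFrame(rec_rows)
    return ScoringResult(feature=feature, s_max=s_max, models=models, records=records, curves=pd.DataFrame(curve_rows))


def predict_score(model: BoundedRegressionMLP, vector: np.ndarray) -> float:
    """Score one slide-feature vector; always inside [0, s_max]."""
    return float(model.predict(np.atleast_2d(vector))[0])


def nas(steatosis: float, inflammation: float, ballooning: float) -> float:
    """NAFLD activity score: steatosis + inflammation + ballooning, range 0-8."""
    for name, value, s_max in (
        ("steatosis", steatosis, 3),
        ("inflammation", inflammation, 3),
        ("ballooning", ballooning, 2),
    ):
        if not 0 <= value <= s_max:
            raise ValueError(f"{name} score {value} outside [0, {s_max}]")
    return float(steatosis + inflammation + ballooning)
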