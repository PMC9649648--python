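"""End-to-end orchestration: tiles -> CNNs -> feature maps -> slide scores.

The stages mirror the scoring workflow: labelled tiles train one CNN per
feature; each trained CNN sweeps every slide's tile grid into a spatial
feature map; maps are aggregated to slide-feature vectors; per-feature
scoring ANNs fit the pathologist scores with 4-fold cross-validation; and
the evaluation battery summarizes agreement.  Every stage is deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import aggregate
from .classifiers import ClassifierSpec, TileClassifier, TrainingHistory, split_tiles, train_classifier
from .feature_map import map_slide
from .features import FEATURES, default_scheme
from .scoring import ScoringResult, train_scoring_ann
from .synthetic import render_tile
from .tiling import load_slide


@dataclass
class TrainingSettings:
    """Desk-scale defaults for one feature's CNN training."""

    n_per_class: int = 32
    epochs: int = 12
    batch_size: int = 32
    lr: float = 2e-3
    input_px: int = 96
    channels: tuple[int, ...] = (16, 32, 48, 64)
    train_frac: float = 0.95


DEFAULT_TRAINING: dict[str, TrainingSettings] = {
    "ballooning": TrainingSettings(n_per_class=64, epochs=14, input_px=96),
    "inflammation": TrainingSettings(n_per_class=64, epochs=14, input_px=96),
    "steatosis": TrainingSettings(n_per_class=24, epochs=10, input_px=96),
    "fibrosis": TrainingSettings(n_per_class=80, epochs=24, input_px=128),
}


def make_training_tiles(
    feature: str,
    n_per_class: int,
    tile_px: int = 299,
    seed: int = 0,
    ignore_fraction: float = 1.0,
    background: str = "mixed",
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic labelled tiles for one feature's classifier.

    Returns ``(tiles, labels)`` with labels as head indices (ignore last).
    ``ignore_fraction`` scales how many ignore tiles are generated relative
    to ``n_per_class``.  Tiles default to mixed-pathology backgrounds so
    classifiers see the co-occurring features they will meet on slides.
    """
    scheme = default_scheme(feature)
    rng = np.random.default_rng(seed)
    tiles, labels = [], []
    class_plan = [(i, int(v)) for i, v in enumerate(scheme.class_values)]
    for head, value in class_plan:
        for _ in range(n_per_class):
            tiles.append(_render(feature, value, tile_px, rng, background))
            labels.append(head)
    for _ in range(int(round(ignore_fraction * n_per_class))):
        tiles.append(_render(feature, "ignore", tile_px, rng, background))
        labels.append(scheme.n_classes)
    return np.stack(tiles), np.asarray(labels, dtype=int)


def _render(feature, value, tile_px, rng, background="mixed"):
    from .synthetic import render_tile

    seed = int(rng.integers(2**31 - 1))
    return render_tile(feature, value, tile_px=tile_px, seed=seed, background=background).image


def train_feature_classifier(
    feature: str,
    settings: TrainingSettings | None = None,
    seed: int = 0,
    init_checkpoint=None,
    pretrained_mode: str = "none",
) -> tuple[TileClassifier, TrainingHistory]:
    """Generate synthetic training tiles and train one feature's CNN."""
    settings = settings or DEFAULT_TRAINING[feature]
    tiles, labels = make_training_tiles(feature, settings.n_per_class, seed=seed)
    tr, va = split_tiles(labels, train_frac=settings.train_frac, seed=seed)
    spec = ClassifierSpec(
        feature=feature,
        input_px=settings.input_px,
        channels=settings.channels,
        pretrained_mode=pretrained_mode,
    )
    return train_classifier(
        spec,
        tiles[tr],
        labels[tr],
        tiles[va],
        labels[va],
        epochs=settings.epochs,
        batch_size=settings.batch_size,
        lr=settings.lr,
        seed=seed,
        init_checkpoint=init_checkpoint,
    )


def slide_feature_table(
    manifest: pd.DataFrame,
    classifiers: dict[str, TileClassifier],
    min_tissue: float = 0.05,
    maps_out: Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Feature-vector rows per feature for every slide in the manifest."""
    from .tiling import build_grid

    tables: dict[str, list[dict]] = {f: [] for f in classifiers}
    for _, rec in manifest.iterrows():
        slide = load_slide(rec["path"], slide_id=rec["slide_id"])
        grids = {scale: build_grid(slide, scale) for scale in {c.spec.scale for c in classifiers.values()}}
        for feature, clf in classifiers.items():
            fm = map_slide(clf, slide, grid=grids[clf.spec.scale], min_tissue=min_tissue)
            if maps_out is not None:
                from .feature_map import export_feature_map

                export_feature_map(fm, maps_out)
            vec = aggregate(fm)
            tables[feature].append(vec.to_row())
    return {f: pd.DataFrame(rows) for f, rows in tables.items()}


def fit_scoring_anns(
    feature_tables: dict[str, pd.DataFrame],
    manifest: pd.DataFrame,
    folds: int = 4,
    epochs: int = 600,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, ScoringResult]]:
    """Cross-validated scoring ANN per feature; returns stacked ScoreRecords."""
    all_records = []
    results: dict[str, ScoringResult] = {}
    truth_by_slide = manifest.set_index("slide_id")
    for feature, table in feature_tables.items():
        x = np.stack([_vector_from_row(row, feature) for _, row in table.iterrows()])
        truth = truth_by_slide.loc[table["slide_id"], feature].to_numpy(dtype=float)
        res = train_scoring_ann(
            x,
            truth,
            feature,
            slide_ids=table["slide_id"].to_numpy(),
            folds=folds,
            epochs=epochs,
            seed=seed,
        )
        results[feature] = res
        all_records.append(res.records)
    return pd.concat(all_records, ignore_index=True), results


def _vector_from_row(row: pd.Series, feature: str) -> np.ndarray:
    k = default_scheme(feature).n_classes
    cols = [f"avg_prob_{i}" for i in range(k)] + ["avg_weighted"] + [f"entropy_{i}" for i in range(k)]
    return row[cols].to_numpy(dtype=float)


def feature_matrix(table: pd.DataFrame, feature: str) -> np.ndarray:
    """(n_slides, 2K+1) matrix in scoring-ANN input order."""
    return np.stack([_vector_from_row(row, feature) for _, row in table.iterrows()])


def run_pipeline(
    cohort_dir,
    out_dir=None,
    features=FEATURES,
    seed: int = 0,
    folds: int = 4,
    training: dict[str, TrainingSettings] | None = None,
    ann_epochs: int = 600,
    min_tissue: float = 0.05,
    export_maps: bool = False,
) -> dict:
    """Full run over a cohort directory containing ``manifest.csv``.

    Trains the tile CNNs on synthetic labelled tiles, maps and aggregates
    every manifest slide, fits the scoring ANNs with cross-validation, and
    writes scores and evaluation tables.  Returns the in-memory artifacts.
    """
    from .evaluation import evaluate_scores, reports_frame
    from .scoring import nas

    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir) if out_dir is not None else cohort_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = cohort_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {cohort_dir}")
    manifest = pd.read_csv(manifest_path)
    for _, rec in manifest.iterrows():
        if not Path(rec["path"]).exists():
            raise FileNotFoundError(f"slide {rec['slide_id']} missing on disk: {rec['path']}")

    training = training or DEFAULT_TRAINING
    classifiers: dict[str, TileClassifier] = {}
    histories: dict[str, TrainingHistory] = {}
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    for i, feature in enumerate(features):
        clf, hist = train_feature_classifier(feature, training.get(feature), seed=seed + 101 * i)
        clf.save(models_dir / f"cnn_{feature}.npz")
        hist.to_csv(models_dir / f"cnn_{feature}_history.csv")
        classifiers[feature] = clf
        histories[feature] = hist

    tables = slide_feature_table(
        manifest, classifiers, min_tissue=min_tissue, maps_out=(out_dir / "maps") if export_maps else None
    )
    for feature, table in tables.items():
        table.to_csv(out_dir / f"features_{feature}.csv", index=False)

    records, results = fit_scoring_anns(tables, manifest, folds=folds, epochs=ann_epochs, seed=seed)
    records.to_csv(out_dir / "score_records.csv", index=False)

    scores = records.pivot_table(index="slide_id", columns="feature", values="ai_score").reset_index()
    if all(f in scores.columns for f in ("steatosis", "inflammation", "ballooning")):
        scores["NAS"] = [
            nas(s, i, b) for s, i, b in zip(scores["steatosis"], scores["inflammation"], scores["ballooning"])
        ]
    scores.to_csv(out_dir / "scores.csv", index=False)

    reports = evaluate_scores(records)
    reports_frame(reports).to_csv(out_dir / "evaluation.csv", index=False)
    return {
        "manifest": manifest,
        "classifiers": classifiers,
        "histories": histories,
        "feature_tables": tables,
        "records": records,
        "scoring": results,
        "scores": scores,
        "reports": reports,
    }
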