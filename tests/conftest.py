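"""Shared fixtures.

The session-scoped ``trained_pipeline`` fixture performs one full
desk-scale end-to-end run (train the four tile CNNs on synthetic labelled
tiles, generate a 120-slide noiseless cohort, map + aggregate every slide,
fit the scoring ANNs with 4-fold cross-validation).  It is shared by the
parameter-recovery, group-comparison and monotonicity tests so the
expensive computation happens once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

COHORT_N = 120
COHORT_SEED = 2024
CNN_SEED = 7


@dataclass
class PipelineArtifacts:
    cohort_dir: object
    manifest: pd.DataFrame
    classifiers: dict
    histories: dict
    feature_tables: dict
    records: pd.DataFrame
    scoring: dict


@pytest.fixture(scope="session")
def trained_classifiers():
    """The four tile CNNs trained once on synthetic labelled tiles."""
    from nashscore.pipeline import train_feature_classifier

    classifiers, histories = {}, {}
    for i, feature in enumerate(["ballooning", "inflammation", "steatosis", "fibrosis"]):
        clf, hist = train_feature_classifier(feature, seed=CNN_SEED + 101 * i)
        classifiers[feature] = clf
        histories[feature] = hist
    return classifiers, histories


@pytest.fixture(scope="session")
def trained_pipeline(tmp_path_factory, trained_classifiers) -> PipelineArtifacts:
    """Full noiseless-cohort run: slides, feature vectors, CV scoring."""
    from nashscore.pipeline import fit_scoring_anns, slide_feature_table
    from nashscore.synthetic import generate_cohort

    classifiers, histories = trained_classifiers
    cohort_dir = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(COHORT_N, cohort_dir, observer_noise_sd=0.0, seed=COHORT_SEED)
    tables = slide_feature_table(manifest, classifiers)
    records, results = fit_scoring_anns(tables, manifest, folds=4, seed=11)
    return PipelineArtifacts(
        cohort_dir=cohort_dir,
        manifest=manifest,
        classifiers=classifiers,
        histories=histories,
        feature_tables=tables,
        records=records,
        scoring=results,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
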