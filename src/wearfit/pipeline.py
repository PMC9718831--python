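"""End-to-end assembly: simulate, clean, featurize, bundle.

Glues the generator, sensor processing and feature extraction into one
:class:`CohortBundle` that the evaluation tasks consume, keeping count
of every exclusion (insufficient wear, unusable series) along the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from wearfit.cohort import (
    CohortConfig,
    DeltaModel,
    ParticipantRecord,
    StudyData,
    generate_trace,
    participants_to_frame,
    participants_truth_frame,
    recover_vo2max,
    simulate_study,
)
from wearfit.features import FeatureRegistry, build_feature_vector, default_registry
from wearfit.processing import process_trace, wear_eligibility


@dataclass
class CohortBundle:
    """Everything the evaluation tasks need, indexed by participant id.

    ``baseline``/``followup`` are the public covariate tables (the
    ``vo2max`` column is the observed submaximal-test value);
    ``truth_baseline``/``truth_followup`` carry the generator latents
    and exist only for scoring; ``oracle_baseline`` holds the analytic
    heart-rate-inverse fitness estimate per participant.
    """

    baseline: pd.DataFrame
    followup: pd.DataFrame
    features_baseline: pd.DataFrame
    features_followup: Optional[pd.DataFrame] = None
    truth_baseline: Optional[pd.DataFrame] = None
    truth_followup: Optional[pd.DataFrame] = None
    oracle_baseline: Optional[pd.Series] = None
    registry: Optional[FeatureRegistry] = None
    exclusions: dict = field(default_factory=dict)

    @property
    def longitudinal_ids(self) -> list[str]:
        return [i for i in self.followup.index if i in self.features_baseline.index]


def _phase_features(records: list[ParticipantRecord], config: CohortConfig,
                    registry: FeatureRegistry, compute_oracle: bool,
                    exclusions: dict):
    rows, oracle = {}, {}
    kept = []
    for rec in records:
        trace = generate_trace(rec, config)
        processed, summary = process_trace(trace)
        if not wear_eligibility(summary):
            exclusions["insufficient_wear"] = exclusions.get("insufficient_wear", 0) + 1
            continue
        try:
            rows[rec.participant_id] = build_feature_vector(rec, processed, registry)
        except ValueError:
            exclusions["unusable_series"] = exclusions.get("unusable_series", 0) + 1
            continue
        if compute_oracle:
            oracle[rec.participant_id] = recover_vo2max(processed, rec, config)
        kept.append(rec)
    features = pd.DataFrame(rows).T if rows else pd.DataFrame()
    features.index.name = "participant_id"
    return kept, features, pd.Series(oracle, name="vo2max_oracle", dtype=float)


def assemble_bundle(study: StudyData, config: CohortConfig,
                    registry: Optional[FeatureRegistry] = None,
                    followup_traces: bool = True,
                    compute_oracle: bool = True) -> CohortBundle:
    """Run every baseline (and optionally follow-up) sensor week through
    processing and feature extraction."""
    registry = registry or default_registry()
    exclusions: dict = {}
    kept_b, feats_b, oracle_b = _phase_features(
        study.baseline, config, registry, compute_oracle, exclusions)
    base = participants_to_frame(kept_b).set_index("participant_id")
    truth_b = participants_truth_frame(kept_b).set_index("participant_id")

    followup_records = [r for r in study.followup
                        if r.participant_id in base.index]
    fu = participants_to_frame(followup_records).set_index("participant_id")
    truth_f = participants_truth_frame(followup_records).set_index("participant_id")
    feats_f = None
    if followup_traces and followup_records:
        _, feats_f, _ = _phase_features(
            followup_records, config, registry, False, exclusions)
    return CohortBundle(
        baseline=base, followup=fu,
        features_baseline=feats_b, features_followup=feats_f,
        truth_baseline=truth_b, truth_followup=truth_f,
        oracle_baseline=oracle_b, registry=registry, exclusions=exclusions,
    )


def simulate_bundle(config: CohortConfig,
                    delta_model: Optional[DeltaModel] = None,
                    longitudinal_fraction: float = 0.25,
                    registry: Optional[FeatureRegistry] = None,
                    followup_traces: bool = True,
                    compute_oracle: bool = True) -> CohortBundle:
    """One call from a config to an analysis-ready bundle."""
    study = simulate_study(config, delta_model, longitudinal_fraction)
    return assemble_bundle(study, config, registry=registry,
                           followup_traces=followup_traces,
                           compute_oracle=compute_oracle)


def oracle_r2(bundle: CohortBundle, ids=None) -> float:
    """Test-set R^2 of the analytic heart-rate-inverse fitness estimate.

    This is the generator-aware benchmark: the best any model could do
    given the observation noise baked into the traces and the
    submaximal-test error on the outcome.
    """
    if bundle.oracle_baseline is None or bundle.oracle_baseline.empty:
        raise ValueError("bundle was built without oracle estimates")
    ids = list(bundle.oracle_baseline.index if ids is None else ids)
    y = bundle.baseline.loc[ids, "vo2max"].to_numpy(float)
    p = bundle.oracle_baseline.loc[ids].to_numpy(float)
    err = y - p
    return float(1.0 - np.sum(err**2) / np.sum((y - y.mean()) ** 2))
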