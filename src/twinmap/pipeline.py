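"""End-to-end stratification pipeline on a (synthetic or real) cohort.

Chains the stages: eligibility and complete-case filtering, reference /
model split, twin calibration and scoring, 3D embedding, mean-shift
stratification and cluster summaries.  Used by the CLI ``report``
subcommand, the validation suites and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import complete_case_filter, eligibility_filter, to_predictor_vectors
from .manifold import ClusterSummary, ManifoldStratifier, summarize_clusters
from .simulate import GeneratorConfig, generate_cohort
from .twin import TwinScorer, split_reference_model


@dataclass
class PipelineResult:
    cohort: pd.DataFrame            # filtered complete-case cohort
    reference: pd.DataFrame
    model_records: pd.DataFrame     # rows aligned with deviations/coords
    scorer: TwinScorer
    deviations: np.ndarray
    manifold: ManifoldStratifier
    summaries: list[ClusterSummary]

    @property
    def major_summaries(self) -> list[ClusterSummary]:
        return [s for s in self.summaries if not s.minor]


def run_stratification(
    cohort: pd.DataFrame,
    seed: int = 0,
    reference_fraction: float = 0.5,
    k_twins: int | None = None,
    manifold_kwargs: dict | None = None,
) -> PipelineResult:
    """Run filtering, twin scoring and manifold stratification on a cohort."""
    df = complete_case_filter(eligibility_filter(cohort))
    reference, model_records = split_reference_model(
        df, fraction=reference_fraction, seed=seed
    )
    scorer = TwinScorer(k_twins=k_twins).fit(to_predictor_vectors(reference))
    deviations = scorer.transform(to_predictor_vectors(model_records))
    manifold = ManifoldStratifier(
        random_state=seed, **(manifold_kwargs or {})
    ).fit(deviations)
    summaries = summarize_clusters(manifold, model_records)
    return PipelineResult(
        cohort=df,
        reference=reference,
        model_records=model_records,
        scorer=scorer,
        deviations=deviations,
        manifold=manifold,
        summaries=summaries,
    )


def run_synthetic_stratification(
    n: int = 2000, seed: int = 0, **kwargs
) -> PipelineResult:
    """Generate a default-profile synthetic cohort and stratify it."""
    cohort = generate_cohort(GeneratorConfig(n=n, seed=seed))
    return run_stratification(cohort, seed=seed, **kwargs)
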