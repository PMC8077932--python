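"""Planted-signal evaluation harness.

Runs the full analysis on a synthetic corpus and scores recovery of the
generator's hidden structure: the improvement-effect ordering (via the
most/least-improved cohorts), covariate balance of the planted
confounder, and the planted side-effect keywords in the SAGE output.
This is the package's own validation loop; the analysis itself never
sees the hidden truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pipeline import PipelineConfig, PipelineResult, analyze
from .synth import SimConfig, generate_population


@dataclass
class ExperimentReport:
    """Truth-based scores for one synthetic end-to-end run."""

    result: PipelineResult
    delta_most: float                 # mean hidden delta, most-improved cohort
    delta_least: float                # mean hidden delta, least-improved cohort
    smd_before: float                 # planted confounder, pre-stratification
    smd_after: float                  # planted confounder, stratum-weighted
    planted_hits_top20: int           # planted improved terms in SAGE top-20
    n_planted: int
    intake_precision: float
    intake_recall: float
    n_users: int


# covariate column used to score balance recovery: log follower count is
# the strongest planted confounder the pipeline actually observes
CONFOUNDER_COLUMN = "struct:n_followers"


def run_synthetic_experiment(
    seed: int,
    sim_config: SimConfig | None = None,
    pipe_config: PipelineConfig | None = None,
) -> ExperimentReport:
    """Generate a corpus, analyze it blind, and score recovery vs truth."""
    sim = sim_config if sim_config is not None else SimConfig()
    sim = replace(sim, seed=seed)
    pipe = pipe_config if pipe_config is not None else PipelineConfig(n_top_unigrams=200)

    timelines = generate_population(sim)
    truth = {tl.user_id: tl.truth for tl in timelines}
    result = analyze(timelines, pipe, seed=seed)

    # intake recovery
    detected = set(result.treated_users)
    actual = {u for u, t in truth.items() if t["is_treatment"]}
    tp = len(detected & actual)
    precision = tp / len(detected) if detected else 0.0
    recall = tp / len(actual) if actual else 0.0

    # hidden-delta ordering of the selected cohorts
    pair = result.cohort_pair
    delta_most = float(np.mean([truth[u]["delta"] for u in pair.most_improved]))
    delta_least = float(np.mean([truth[u]["delta"] for u in pair.least_improved]))

    # balance of the planted confounder
    row = result.balance.loc[CONFOUNDER_COLUMN]
    smd_before, smd_after = float(row["smd_before"]), float(row["smd_after"])

    # planted keywords in the most-improved SAGE list
    kw = result.sage_keywords
    top_most = set(
        kw.loc[kw["target_label"] == "most_improved", "term"].head(20)
    )
    planted = set(sim.planted_terms_improved)
    hits = sum(1 for term in planted if term in top_most)

    return ExperimentReport(
        result=result,
        delta_most=delta_most,
        delta_least=delta_least,
        smd_before=smd_before,
        smd_after=smd_after,
        planted_hits_top20=hits,
        n_planted=len(planted),
        intake_precision=precision,
        intake_recall=recall,
        n_users=sim.n_treatment + sim.n_control,
    )


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Derive a per-replicate seed below 2^31 from one base seed."""
    return (base_seed * 9973 + replicate * 7919 + 1) % (2**31)
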