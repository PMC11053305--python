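"""Shared configuration for the numbered analysis drivers.

The discovery cohort mimics a hospital case/control study sampled at
diagnosis; the evaluation cohort is a longitudinal pre-diagnosis cohort
drawn from the same seed-derived bin-level biology.  Intermediate files
live under ``scratch/`` (regenerated on demand), final tables under
``results/``.
"""

import dataclasses
from pathlib import Path

from fragscreen import synthetic_data as sd

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 303

DISCOVERY_CONFIG = sd.CohortConfig(
    seed=SEED, n_cases=60, n_controls=60, n_bins=50, n_arms=5,
    n_affected_bins=5, enrichment_range=(2.0, 2.0), tumor_fraction=0.5,
    fragments_per_sample=100_000, sampling_times_years=(0.0,),
)

EVALUATION_CONFIG = dataclasses.replace(
    DISCOVERY_CONFIG, n_cases=220, n_controls=200,
    sampling_times_years=(5.0, 3.5, 2.5, 1.5, 0.5),
)

MODEL_PATH = SCRATCH / "fragmentation_model.json"


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
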