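"""Shared setup for the analysis scripts: one deterministic study cohort.

Every script regenerates the same synthetic multiplexed study (3 patients,
default noise: 5 % ADO / 5 % missing / 5 % doublets) from a fixed seed and
runs the stages it needs; generation takes well under a second, so no
intermediate matrices need to be stored.  Small result tables go under
``results/``.
"""

from __future__ import annotations

from pathlib import Path

from scmrd.demux import build_profile_database, demultiplex_run
from scmrd.synthio import CohortConfig, default_cohort, generate_multiplex_run

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_runs():
    """Diagnosis and remission multiplexed runs for the default cohort."""
    runs = {}
    for timepoint, seed in (("diagnosis", SEED), ("remission", SEED + 1)):
        cfg = default_cohort(3, seed=seed, n_cells=6000, timepoints=timepoint)
        runs[timepoint] = generate_multiplex_run(cfg)
    return runs


def demuxed_partitions(run):
    matrix, antibody, profiles, truth = run
    db = build_profile_database(profiles)
    return demultiplex_run(matrix, antibody, db, None), truth


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
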