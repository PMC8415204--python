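"""Named study/pipeline profiles.

``default_config`` carries the study conditions the package emulates
(15 subjects, 2 drugs x 4 sessions, 90 nodes, 300-s recordings at
600 Hz, 2-s epochs).  ``ci_config`` keeps every design quantity of the
default — subjects, nodes, duration, epoching, effects, template — but
samples the carrier at 150 Hz instead of 600 Hz; the 1-s envelope
statistics that all downstream measures are built from are unchanged,
while raw-signal processing is four times cheaper.  ``mini_config`` is
a deliberately small study (10 subjects, 24 nodes, 180 s) for
repeated-seed calibration and specificity checks, and ``smoke_config``
is the minimal schema-exercising configuration.
"""

from __future__ import annotations

from dataclasses import replace

from .config import PipelineConfig
from .synth import StudyConfig, StudyDesign


def default_config(seed: int = 0) -> PipelineConfig:
    """Full-scale study conditions (600 Hz); heavy on one CPU."""
    return PipelineConfig(study=StudyConfig(seed=seed), seed=seed)


def ci_config(seed: int = 0, n_perm: int = 2000) -> PipelineConfig:
    """Default design at a 150 Hz carrier rate: the routine test scale."""
    return PipelineConfig(
        study=StudyConfig(fs=150.0, seed=seed),
        n_perm=n_perm,
        seed=seed,
    )


def mini_config(seed: int = 0, n_perm: int = 1000) -> PipelineConfig:
    """Small study for repeated-seed calibration/specificity runs."""
    return PipelineConfig(
        study=StudyConfig(
            design=StudyDesign(n_subjects=10),
            n_nodes=24,
            duration_s=180.0,
            fs=150.0,
            seed=seed,
        ),
        n_perm=n_perm,
        seed=seed,
    )


def smoke_config(seed: int = 0) -> PipelineConfig:
    """Two subjects, two nodes, 60 s: schema and plumbing only."""
    return PipelineConfig(
        study=StudyConfig(
            design=StudyDesign(n_subjects=2),
            n_nodes=2,
            duration_s=60.0,
            fs=150.0,
            seed=seed,
        ),
        n_perm=100,
        seed=seed,
    )
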