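"""Shared fixtures.

The heavy end-to-end fixtures (one CI-profile study analysis, ten
mini-profile studies for specificity) are session-scoped so that every
test needing them shares a single run.
"""

from __future__ import annotations

import numpy as np
import pytest

from oscillomap.pipeline import run_full_pipeline
from oscillomap.profiles import ci_config, mini_config
from oscillomap.synth import generate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def ci_run(tmp_path_factory):
    """One full CI-profile study (default design, 150 Hz carrier) analysed
    end to end; returns (config, report, run_dir, study)."""
    cfg = ci_config(seed=11)
    run_dir = tmp_path_factory.mktemp("ci_run")
    report = run_full_pipeline(cfg, run_dir)
    study = generate_study(cfg.study)
    return cfg, report, run_dir, study


@pytest.fixture(scope="session")
def mini_placebo_counts(tmp_path_factory):
    """Placebo-arm omnibus-significant edge counts over ten mini studies."""
    counts = []
    for k in range(10):
        cfg = mini_config(500 + k)
        run_dir = tmp_path_factory.mktemp(f"mini_{k}")
        rep = run_full_pipeline(cfg, run_dir)
        b = rep["bands"]["alpha"]
        counts.append(
            sum(
                len(b["significant_edge_ids"].get(f"placebo/{t}", []))
                for t in ("post1", "post2", "post3")
            )
        )
    return counts
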