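#!/usr/bin/env python
"""Simulate the synthetic pharmacological study.

Generates the default-design study (15 subjects, active vs placebo, four
sessions, 90 nodes, 300-s recordings) at the 150 Hz evaluation rate,
writes the latent per-cell parameters and receptor template to
results/study.h5 (+ JSON sidecar with the ground truth), and prints what
was planted: which edges are reduced, which nodes gain or lose envelope
dispersion, and the template's attained spatial correlation.

Recordings themselves are regenerable from the seed and are not
materialized here (a full-scale raw dump is several GB).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oscillomap.profiles import ci_config
from oscillomap.storage import write_study_h5, write_template_tsv
from oscillomap.synth import generate_study

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 11


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = ci_config(seed=SEED)
    study = generate_study(cfg.study)
    write_study_h5(study, OUT / "study.h5", materialize=False)
    write_template_tsv(study.template, OUT / "template.tsv")

    gt = study.ground_truth
    print(f"study seed {SEED}: {study.n_recordings} recordings, "
          f"{cfg.study.n_nodes} nodes, {cfg.study.duration_s:.0f} s at "
          f"{cfg.study.fs:.0f} Hz")
    print(f"planted connectivity reductions: {len(gt['affected_edges'])} edges "
          f"(factor {study.effect_spec.edge_effect} on latent coupling), e.g. "
          f"{gt['affected_edges'][:3]}")
    print(f"planted activity changes: dispersion x{study.effect_spec.activity_effect_up} "
          f"on {len(gt['affected_nodes_up'])} frontal nodes, "
          f"x{study.effect_spec.activity_effect_down} on "
          f"{len(gt['affected_nodes_down'])} posterior nodes")
    print(f"template: target rho {gt['template_target_rho']}, attained "
          f"{gt['template_attained_rho']:.3f} against the |effect| map")
    print(f"wrote {OUT/'study.h5'} (+ .json sidecar) and {OUT/'template.tsv'}")


if __name__ == "__main__":
    main()
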