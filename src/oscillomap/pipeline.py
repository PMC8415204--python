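"""End-to-end orchestration: simulate -> envelopes -> connectivity and
activity stacks -> standardization -> pruning -> RM-ANOVA -> post-hocs
-> template spatial correlation.

Recordings are streamed (generated, reduced to envelopes, discarded) so
full-scale studies never sit in memory at once.  Every stage failure is
re-raised with a stage label; every run report carries the full config
echo and seed so outputs are reproducible byte for byte.
"""

from __future__ import annotations

import time
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .activity import activity_from_envelopes, standardize_activity
from .bands import BandDefinition
from .config import PipelineConfig, config_to_dict
from .envelope import (
    bandpass,
    concatenate_epochs,
    downsample_envelope,
    hilbert_envelope,
    median_filter_envelope,
    symmetric_orthogonalize,
)
from .inference import (
    FeaturePanel,
    bh_fdr,
    permutation_posthoc_family,
    rm_anova_per_feature,
    spatial_correlation_test,
)
from .recording import EnvelopeSet, EpochedRecording
from .standardize import mean_rank_mask, standardize_session, surrogate_normalize
from .storage import (
    edges_long_format,
    write_edge_table,
    write_json_report,
    write_map_table,
    write_table,
    write_template_tsv,
)
from .synth import SyntheticStudy, generate_study


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def band_envelopes(
    rec: EpochedRecording,
    band: BandDefinition,
    median_k: int = 3,
) -> tuple[EnvelopeSet, EnvelopeSet]:
    """(connectivity, activity) envelope sets sharing one band-pass pass.

    The connectivity set is leakage-corrected (symmetric
    orthogonalization); the activity set is not.
    """
    filtered = bandpass(rec, band)
    series = concatenate_epochs(filtered)

    def finish(x: np.ndarray) -> EnvelopeSet:
        env = hilbert_envelope(x)
        env_1s = downsample_envelope(
            env, rec.fs, band, node_labels=rec.node_labels, meta=rec.meta
        )
        return median_filter_envelope(env_1s, k=median_k)

    return finish(symmetric_orthogonalize(series)), finish(series)


def run_full_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    study: Optional[SyntheticStudy] = None,
) -> dict:
    """Run simulation (unless a study is supplied) and the full analysis.

    Writes tidy TSV tables plus a JSON run report under ``out_dir`` and
    returns the report.  Stages that the configured design cannot
    support (e.g. group statistics with fewer than 3 subjects, or
    noise-peak session standardisation with fewer than 50 features) are
    skipped and listed in the report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {
        "config": config_to_dict(config),
        "version": __version__,
        "stages_skipped": [],
        "bands": {},
    }

    with _stage("simulate"):
        if study is None:
            study = generate_study(config.study)
        design = study.design
        n_nodes = study.config.n_nodes
        n_edges = n_nodes * (n_nodes - 1) // 2
        report["n_recordings"] = study.n_recordings
        report["n_nodes"] = n_nodes
        report["n_edges"] = n_edges
        write_template_tsv(study.template, out_dir / "template.tsv")

    can_standardize_edges = n_edges >= 50
    can_standardize_nodes = n_nodes >= 50
    can_infer = design.n_subjects >= 3
    if not can_standardize_edges:
        report["stages_skipped"].append(
            "session standardization (edges): fewer than 50 edges"
        )
    if not can_standardize_nodes:
        report["stages_skipped"].append(
            "session standardization (nodes): fewer than 50 nodes"
        )
    if not can_infer:
        report["stages_skipped"].append(
            "group statistics: fewer than 3 subjects"
        )

    for bi, band in enumerate(config.bands):
        breport: dict = {"noise_peak_fits": {}}
        report["bands"][band.name] = breport
        conn: dict[tuple[str, str, str], np.ndarray] = {}
        act: dict[tuple[str, str, str], np.ndarray] = {}

        with _stage(f"envelopes+connectivity[{band.name}]"):
            for ri, rec in enumerate(study.iter_recordings()):
                key = rec.meta.as_tuple()
                env_conn, env_act = band_envelopes(rec, band, config.median_k)
                sseed = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(100 + bi, ri)
                )
                cm = surrogate_normalize(
                    env_conn, n_surrogates=config.n_surrogates, seed=sseed
                )
                if can_standardize_edges:
                    cm, fit = standardize_session(cm)
                    breport["noise_peak_fits"]["/".join(key) + "/edges"] = {
                        "mu": fit.mu, "sigma": fit.sigma, "n_used": fit.n_used,
                    }
                conn[key] = cm.values
                amap = activity_from_envelopes(env_act)
                if can_standardize_nodes:
                    amap, afit = standardize_activity(amap)
                    breport["noise_peak_fits"]["/".join(key) + "/nodes"] = {
                        "mu": afit.mu, "sigma": afit.sigma, "n_used": afit.n_used,
                    }
                act[key] = amap.values

        with _stage(f"edge pruning[{band.name}]"):
            mask = mean_rank_mask(list(conn.values()), config.retain_fraction)
            ei, ej = mask.edge_indices()
            breport["n_edges_total"] = n_edges
            breport["n_edges_retained"] = mask.n_retained
            write_table(
                pd.DataFrame({"node_i": ei, "node_j": ej}),
                out_dir / f"mask_{band.name}.tsv",
                sort_by=["node_i", "node_j"],
            )

        with _stage(f"export[{band.name}]"):
            edge_rows = [
                edges_long_format(
                    v, band=band.name, subject=k[0], drug=k[1], session=k[2],
                    stage="z_session" if can_standardize_edges else "z_surrogate",
                )
                for k, v in conn.items()
            ]
            write_edge_table(
                pd.concat(edge_rows, ignore_index=True),
                out_dir / f"edges_{band.name}.tsv",
            )
            map_rows = []
            for k, v in act.items():
                df = pd.DataFrame({"node": np.arange(n_nodes), "value": v})
                df["band"], df["subject"], df["drug"], df["session"] = (
                    band.name, k[0], k[1], k[2],
                )
                df["stage"] = "z_session" if can_standardize_nodes else "cov"
                map_rows.append(df)
            write_map_table(
                pd.concat(map_rows, ignore_index=True),
                out_dir / f"activity_{band.name}.tsv",
            )

        if not can_infer:
            continue

        with _stage(f"rm-anova edges[{band.name}]"):
            edge_ids = [f"{i}-{j}" for i, j in zip(ei, ej)]
            edge_vals = np.empty(
                (design.n_subjects, len(design.drugs), len(design.sessions), len(edge_ids))
            )
            for si_, s in enumerate(design.subjects):
                for di_, d in enumerate(design.drugs):
                    for ti_, t in enumerate(design.sessions):
                        edge_vals[si_, di_, ti_] = conn[(s, d, t)][ei, ej]
            edge_panel = FeaturePanel(
                values=edge_vals, feature_ids=edge_ids,
                subjects=list(design.subjects), drugs=list(design.drugs),
                sessions=list(design.sessions), band=band.name,
            )
            anova_e = rm_anova_per_feature(edge_panel)
            write_table(
                pd.DataFrame(
                    {
                        "feature": anova_e.feature_ids,
                        "F_drug": anova_e.F_drug, "p_drug": anova_e.p_drug,
                        "F_session": anova_e.F_session, "p_session": anova_e.p_session,
                        "F_interaction": anova_e.F_interaction,
                        "p_interaction": anova_e.p_interaction,
                    }
                ),
                out_dir / f"anova_edges_{band.name}.tsv",
                sort_by=["feature"],
            )

        with _stage(f"posthoc edges[{band.name}]"):
            if config.posthoc_gate == "interaction":
                gate = anova_e.p_interaction < config.alpha
            else:
                gate = np.ones(len(edge_ids), dtype=bool)
            breport["n_edges_gated"] = int(gate.sum())
            posthoc_edge_rows = []
            sig_edges: dict[str, list[str]] = {}
            if gate.any():
                gated_panel = FeaturePanel(
                    values=edge_vals[:, :, :, gate],
                    feature_ids=[f for f, g in zip(edge_ids, gate) if g],
                    subjects=list(design.subjects), drugs=list(design.drugs),
                    sessions=list(design.sessions), band=band.name,
                )
                contrasts = [
                    (d, t) for d in design.drugs for t in design.post_sessions
                ]
                family = permutation_posthoc_family(
                    gated_panel, contrasts, n_perm=config.n_perm,
                    seed=np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(200 + bi,)
                    ),
                )
                for (d, t), res in family.items():
                    sig = [
                        f for f, p in zip(res.feature_ids, res.p_corrected)
                        if p < config.alpha
                    ]
                    sig_edges[f"{d}/{t}"] = sig
                    posthoc_edge_rows.append(
                        pd.DataFrame(
                            {
                                "feature": res.feature_ids,
                                "drug": d, "session": t,
                                "t": res.t,
                                "p_uncorrected": res.p_uncorrected,
                                "p_corrected": res.p_corrected,
                                "direction": res.direction,
                            }
                        )
                    )
            breport["significant_edges"] = {
                k: len(v) for k, v in sig_edges.items()
            }
            breport["significant_edge_ids"] = sig_edges
            if posthoc_edge_rows:
                write_table(
                    pd.concat(posthoc_edge_rows, ignore_index=True),
                    out_dir / f"posthoc_edges_{band.name}.tsv",
                    sort_by=["drug", "session", "feature"],
                )

        with _stage(f"rm-anova activity[{band.name}]"):
            node_ids = [str(i) for i in range(n_nodes)]
            node_vals = np.empty(
                (design.n_subjects, len(design.drugs), len(design.sessions), n_nodes)
            )
            for si_, s in enumerate(design.subjects):
                for di_, d in enumerate(design.drugs):
                    for ti_, t in enumerate(design.sessions):
                        node_vals[si_, di_, ti_] = act[(s, d, t)]
            node_panel = FeaturePanel(
                values=node_vals, feature_ids=node_ids,
                subjects=list(design.subjects), drugs=list(design.drugs),
                sessions=list(design.sessions), band=band.name,
            )
            anova_n = rm_anova_per_feature(node_panel)
            inter_reject, inter_adj = bh_fdr(anova_n.p_interaction, config.fdr_q)
            breport["n_nodes_interaction_fdr"] = int(inter_reject.sum())
            write_table(
                pd.DataFrame(
                    {
                        "node": node_ids,
                        "F_drug": anova_n.F_drug, "p_drug": anova_n.p_drug,
                        "F_session": anova_n.F_session, "p_session": anova_n.p_session,
                        "F_interaction": anova_n.F_interaction,
                        "p_interaction": anova_n.p_interaction,
                        "p_interaction_fdr": inter_adj,
                    }
                ),
                out_dir / f"anova_nodes_{band.name}.tsv",
                sort_by=["node"],
            )

        with _stage(f"posthoc activity[{band.name}]"):
            posthoc_node_rows = []
            t_maps: dict[str, np.ndarray] = {}
            n = design.n_subjects
            pre_i = design.sessions.index("pre")
            for di_, d in enumerate(design.drugs):
                for t in design.post_sessions:
                    ti_ = design.sessions.index(t)
                    diffs = node_vals[:, di_, ti_, :] - node_vals[:, di_, pre_i, :]
                    sd = diffs.std(axis=0, ddof=1)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        tvec = diffs.mean(axis=0) / (sd / np.sqrt(n))
                    tvec = np.where(sd == 0, 0.0, tvec)
                    p_t = 2 * st_t_sf(np.abs(tvec), n - 1)
                    if config.posthoc_gate == "interaction":
                        gate_n = inter_reject
                    else:
                        gate_n = np.ones(n_nodes, dtype=bool)
                    p_for_fdr = p_t[gate_n]
                    rej = np.zeros(n_nodes, dtype=bool)
                    adj = np.ones(n_nodes)
                    if p_for_fdr.size:
                        r_, a_ = bh_fdr(p_for_fdr, config.fdr_q)
                        rej[gate_n] = r_
                        adj[gate_n] = a_
                    t_maps[f"{d}/{t}"] = tvec
                    posthoc_node_rows.append(
                        pd.DataFrame(
                            {
                                "node": node_ids, "drug": d, "session": t,
                                "t": tvec, "p_uncorrected": p_t,
                                "p_fdr": adj, "significant": rej,
                                "gated": gate_n,
                            }
                        )
                    )
            write_table(
                pd.concat(posthoc_node_rows, ignore_index=True),
                out_dir / f"posthoc_nodes_{band.name}.tsv",
                sort_by=["drug", "session", "node"],
            )
            breport["significant_nodes"] = {
                f"{d}/{t}": int(
                    df.loc[(df.drug == d) & (df.session == t), "significant"].sum()
                )
                for df in [pd.concat(posthoc_node_rows, ignore_index=True)]
                for d in design.drugs
                for t in design.post_sessions
            }

        with _stage(f"template correlation[{band.name}]"):
            active = study.effect_spec.applies_to_drug
            family = {
                t: np.abs(t_maps[f"{active}/{t}"])
                for t in design.post_sessions
            }
            results = spatial_correlation_test(
                family, study.template, n_perm=config.n_perm,
                seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(300 + bi,)),
            )
            breport["template_correlation"] = {
                r.name: {"r": r.r, "p_corrected": r.p_corrected} for r in results
            }
            write_table(
                pd.DataFrame(
                    {
                        "session": [r.name for r in results],
                        "r": [r.r for r in results],
                        "p_corrected": [r.p_corrected for r in results],
                        "n_perm": [r.n_perm for r in results],
                    }
                ),
                out_dir / f"template_correlation_{band.name}.tsv",
                sort_by=["session"],
            )

    report["runtime_s"] = round(time.time() - t0, 2)
    report["seed"] = config.seed
    write_json_report(report, out_dir / "report.json")
    return report


def st_t_sf(x, df):
    """Student-t survival function (kept separate for clarity in the maps)."""
    from scipy import stats

    return stats.t.sf(x, df)
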