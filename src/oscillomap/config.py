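"""Pipeline configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .bands import DEFAULT_BANDS, BandDefinition, band_by_name
from .synth import EffectSpec, StudyConfig, StudyDesign


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the simulate-and-analyse pipeline.

    Simulation parameters live in ``study``; the remaining fields
    control the analysis chain.  ``analysis_bands`` selects which of the
    named bands are analysed (default: just the study's carrier band,
    since the synthetic signal is band-limited).
    """

    study: StudyConfig = field(default_factory=StudyConfig)
    analysis_bands: tuple[str, ...] = ("alpha",)
    retain_fraction: float = 0.2
    n_surrogates: int = 100
    n_perm: int = 5000
    fdr_q: float = 0.05
    alpha: float = 0.05
    median_k: int = 3
    posthoc_gate: str = "interaction"   # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.retain_fraction <= 1:
            raise ValueError("retain_fraction must be in (0, 1]")
        if self.n_surrogates < 50:
            raise ValueError("n_surrogates must be >= 50")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.median_k < 1 or self.median_k % 2 == 0:
            raise ValueError("median_k must be odd and >= 1")
        if self.posthoc_gate not in ("interaction", "none"):
            raise ValueError("posthoc_gate must be 'interaction' or 'none'")
        for name in self.analysis_bands:
            band_by_name(name)

    @property
    def bands(self) -> tuple[BandDefinition, ...]:
        return tuple(band_by_name(n) for n in self.analysis_bands)


_STUDY_KEYS = {
    "n_nodes", "duration_s", "fs", "epoch_length_s", "carrier_band",
    "log_env_sd", "noise_floor", "subject_corr_sd", "n_blocks",
    "within_block_corr", "between_block_corr", "template_rho", "seed",
}
_DESIGN_KEYS = {"n_subjects", "drugs", "sessions"}
_EFFECT_KEYS = {
    "affected_edges", "edge_effect", "affected_nodes_up",
    "affected_nodes_down", "activity_effect_up", "activity_effect_down",
    "applies_to_drug",
}
_TOP_KEYS = {
    "study", "design", "effect", "analysis_bands", "retain_fraction",
    "n_surrogates", "n_perm", "fdr_q", "alpha", "median_k",
    "posthoc_gate", "seed",
}


def _reject_unknown(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ValueError(f"unknown configuration key(s) in {where}: {unknown}")


def config_from_dict(raw: Optional[Mapping[str, Any]]) -> PipelineConfig:
    """Build a validated PipelineConfig from a (possibly empty) mapping."""
    raw = dict(raw or {})
    _reject_unknown(raw, _TOP_KEYS, "top level")

    design_raw = dict(raw.pop("design", {}) or {})
    _reject_unknown(design_raw, _DESIGN_KEYS, "design")
    design = StudyDesign(
        n_subjects=int(design_raw.get("n_subjects", 15)),
        drugs=tuple(design_raw.get("drugs", ("active", "placebo"))),
        sessions=tuple(design_raw.get("sessions", ("pre", "post1", "post2", "post3"))),
    )

    effect_raw = raw.pop("effect", None)
    effect = None
    if effect_raw is not None:
        effect_raw = dict(effect_raw)
        _reject_unknown(effect_raw, _EFFECT_KEYS, "effect")
        if "affected_edges" in effect_raw:
            effect_raw["affected_edges"] = tuple(
                tuple(int(x) for x in e) for e in effect_raw["affected_edges"]
            )
        for key in ("affected_nodes_up", "affected_nodes_down"):
            if key in effect_raw:
                effect_raw[key] = tuple(int(x) for x in effect_raw[key])
        effect = EffectSpec(**effect_raw)

    study_raw = dict(raw.pop("study", {}) or {})
    _reject_unknown(study_raw, _STUDY_KEYS, "study")
    if "carrier_band" in study_raw:
        study_raw["carrier_band"] = band_by_name(study_raw["carrier_band"])
    seed = int(raw.pop("seed", study_raw.get("seed", 0)))
    study_raw.setdefault("seed", seed)
    study = StudyConfig(design=design, effect_spec=effect, **study_raw)

    if "analysis_bands" in raw:
        raw["analysis_bands"] = tuple(raw["analysis_bands"])
    return PipelineConfig(study=study, seed=seed, **raw)


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    """Serialise a PipelineConfig to plain YAML/JSON-safe types."""
    s = cfg.study
    effect = s.effect_spec
    out: dict[str, Any] = {
        "design": {
            "n_subjects": s.design.n_subjects,
            "drugs": list(s.design.drugs),
            "sessions": list(s.design.sessions),
        },
        "study": {
            "n_nodes": s.n_nodes,
            "duration_s": s.duration_s,
            "fs": s.fs,
            "epoch_length_s": s.epoch_length_s,
            "carrier_band": s.carrier_band.name,
            "log_env_sd": s.log_env_sd,
            "noise_floor": s.noise_floor,
            "subject_corr_sd": s.subject_corr_sd,
            "n_blocks": s.n_blocks,
            "within_block_corr": s.within_block_corr,
            "between_block_corr": s.between_block_corr,
            "template_rho": s.template_rho,
            "seed": s.seed,
        },
        "analysis_bands": list(cfg.analysis_bands),
        "retain_fraction": cfg.retain_fraction,
        "n_surrogates": cfg.n_surrogates,
        "n_perm": cfg.n_perm,
        "fdr_q": cfg.fdr_q,
        "alpha": cfg.alpha,
        "median_k": cfg.median_k,
        "posthoc_gate": cfg.posthoc_gate,
        "seed": cfg.seed,
    }
    if effect is not None:
        out["effect"] = {
            "affected_edges": [list(e) for e in effect.affected_edges],
            "edge_effect": _factor_to_plain(effect.edge_effect),
            "affected_nodes_up": list(effect.affected_nodes_up),
            "affected_nodes_down": list(effect.affected_nodes_down),
            "activity_effect_up": _factor_to_plain(effect.activity_effect_up),
            "activity_effect_down": _factor_to_plain(effect.activity_effect_down),
            "applies_to_drug": effect.applies_to_drug,
        }
    return out


def _factor_to_plain(v):
    if isinstance(v, Mapping):
        return {str(k): float(x) for k, x in v.items()}
    return float(v)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, Mapping):
        raise ValueError(f"config file {path} does not contain a mapping")
    return config_from_dict(raw)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
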