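"""Synthetic multi-subject pharmacological study generator.

Emulates the structure of a placebo-controlled crossover
electrophysiology study: per subject, one resting recording per
(drug in {active, placebo}) x (session in {pre, post1, post2, post3})
cell, each a 90-node, 2-s-epoched, band-limited time series whose slow
amplitude envelopes carry a controlled correlation structure.

Signal model per node j:

    x_j(t) = e_j(t) * c_j(t) + noise_floor * w_j(t)

where c_j is unit-variance band-pass filtered white noise (the carrier),
w_j is broadband white noise, and the envelope e_j = exp(sigma_j * g_j)
is the exponential of a slow (< ~0.3 Hz) Gaussian process; the g_j are
correlated across nodes with a prescribed latent correlation matrix.
Envelopes are therefore positive, smooth and log-normal, and their
sample correlations increase monotonically with the latent targets.

Drug effects are injected by scaling latent envelope correlations on a
set of affected edges (connectivity reductions) and scaling the
log-envelope SD on affected nodes (activity changes), for the active
drug at post sessions only.  A receptor-density template whose values
co-vary with the per-node effect magnitude at a controlled spatial
correlation completes the study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
from scipy import signal

from .bands import ALPHA, BandDefinition
from .recording import EpochedRecording, RecordingMeta

__all__ = [
    "StudyDesign",
    "EffectSpec",
    "ReceptorTemplate",
    "StudyConfig",
    "SyntheticStudy",
    "generate_recording",
    "apply_effect_spec",
    "generate_template",
    "generate_study",
    "base_correlation_matrix",
    "nearest_correlation_psd",
]


@dataclass(frozen=True)
class StudyDesign:
    """Crossover design: every subject contributes one recording per cell."""

    n_subjects: int = 15
    drugs: tuple[str, ...] = ("active", "placebo")
    sessions: tuple[str, ...] = ("pre", "post1", "post2", "post3")

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if len(set(self.drugs)) != len(self.drugs) or not self.drugs:
            raise ValueError("drug labels must be unique and nonempty")
        if len(set(self.sessions)) != len(self.sessions) or not self.sessions:
            raise ValueError("session labels must be unique and nonempty")
        if self.sessions[0] != "pre":
            raise ValueError("first session must be the 'pre' baseline")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(f"sub{i + 1:02d}" for i in range(self.n_subjects))

    @property
    def post_sessions(self) -> tuple[str, ...]:
        return self.sessions[1:]

    @property
    def n_cells(self) -> int:
        return self.n_subjects * len(self.drugs) * len(self.sessions)


def _session_factor(value, session: str) -> float:
    """Resolve a scalar-or-per-session-mapping factor for one session."""
    if isinstance(value, Mapping):
        return float(value.get(session, 1.0))
    return float(value)


@dataclass(frozen=True)
class EffectSpec:
    """Which edges/nodes the active drug perturbs, and by how much.

    ``edge_effect`` multiplies the latent envelope correlation of each
    affected edge at post sessions (< 1 means a connectivity reduction);
    ``activity_effect_up``/``_down`` multiply the log-envelope SD of the
    up-/down-affected nodes (> 1 raises envelope dispersion and hence the
    coefficient of variation).  Factors may be scalars (all post
    sessions) or mappings ``session -> factor``.  Pre-session factors
    are implicitly 1.
    """

    affected_edges: tuple[tuple[int, int], ...] = ()
    edge_effect: float | Mapping[str, float] = 1.0
    affected_nodes_up: tuple[int, ...] = ()
    affected_nodes_down: tuple[int, ...] = ()
    activity_effect_up: float | Mapping[str, float] = 1.0
    activity_effect_down: float | Mapping[str, float] = 1.0
    applies_to_drug: str = "active"

    def __post_init__(self) -> None:
        for i, j in self.affected_edges:
            if i == j or i < 0 or j < 0:
                raise ValueError(f"invalid edge ({i}, {j})")
        for f in self._all_factors():
            if not f > 0:
                raise ValueError(f"effect factors must be strictly positive, got {f}")

    def _all_factors(self):
        for v in (
            self.edge_effect,
            self.activity_effect_up,
            self.activity_effect_down,
        ):
            if isinstance(v, Mapping):
                yield from (float(x) for x in v.values())
            else:
                yield float(v)

    def validate_nodes(self, n_nodes: int) -> None:
        idx = [i for e in self.affected_edges for i in e]
        idx += list(self.affected_nodes_up) + list(self.affected_nodes_down)
        if idx and max(idx) >= n_nodes:
            raise ValueError(
                f"effect spec references node {max(idx)} but study has "
                f"{n_nodes} nodes"
            )

    def node_effect_magnitude(self, n_nodes: int) -> np.ndarray:
        """|activity factor - 1| per node: the true activity-effect size map."""
        mag = np.zeros(n_nodes)
        up = _session_factor(self.activity_effect_up, "post1")
        down = _session_factor(self.activity_effect_down, "post1")
        mag[list(self.affected_nodes_up)] = abs(up - 1.0)
        mag[list(self.affected_nodes_down)] = abs(down - 1.0)
        return mag


@dataclass(frozen=True)
class ReceptorTemplate:
    """Node-labelled receptor-density map (arbitrary units, nonnegative)."""

    node_values: np.ndarray
    target_rho: float

    def __post_init__(self) -> None:
        v = np.asarray(self.node_values, dtype=float)
        if v.ndim != 1:
            raise ValueError("template values must be a 1-D per-node vector")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("template values must be finite and nonnegative")
        object.__setattr__(self, "node_values", v)

    @property
    def n_nodes(self) -> int:
        return len(self.node_values)


def nearest_correlation_psd(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix with unit diagonal.

    Eigenvalue clipping at zero followed by re-normalization of the
    diagonal; raises if the result cannot be normalized (zero diagonal).
    """
    c = np.asarray(corr, dtype=float)
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    if w[0] >= -eps:
        out = c.copy()
    else:
        w = np.clip(w, 0.0, None)
        out = (v * w) @ v.T
    d = np.diag(out).copy()
    if np.any(d <= 0):
        raise ValueError("matrix not repairable to a PSD correlation matrix")
    scale = 1.0 / np.sqrt(d)
    out = out * scale[:, None] * scale[None, :]
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def _check_correlation(corr: np.ndarray, n_nodes: int) -> np.ndarray:
    c = np.asarray(corr, dtype=float)
    if c.shape != (n_nodes, n_nodes):
        raise ValueError(f"envelope_corr must be {n_nodes}x{n_nodes}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("envelope_corr must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError("envelope_corr must have a unit diagonal")
    w = np.linalg.eigvalsh((c + c.T) / 2.0)
    if w[0] < -1e-8:
        raise ValueError(
            f"envelope_corr is not positive semi-definite "
            f"(smallest eigenvalue {w[0]:.3e})"
        )
    return (c + c.T) / 2.0


#: Sampling rate (Hz) of the latent envelope process before upsampling.
_LATENT_FS = 4.0
#: Low-pass corner (Hz) of the latent envelope process.
_LATENT_CUTOFF = 0.3


def _latent_envelopes(
    n_nodes: int,
    n_samples: int,
    fs: float,
    envelope_corr: np.ndarray,
    log_sd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated log-normal slow envelopes, upsampled to fs. Shape (n, T)."""
    duration = n_samples / fs
    pad = int(round(_LATENT_FS * 30))  # 30 s padding against filter edges
    t_lat = int(np.ceil(duration * _LATENT_FS)) + 1
    x = rng.standard_normal((t_lat + 2 * pad, n_nodes))
    sos = signal.butter(4, _LATENT_CUTOFF, btype="lowpass", fs=_LATENT_FS, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=0)[pad:-pad]
    # standardize columns so log-envelope SD is exactly log_sd per realization
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    # correlate across nodes; small jitter keeps Cholesky defined at the
    # PSD boundary (rank-deficient targets)
    L = np.linalg.cholesky(envelope_corr + 1e-9 * np.eye(n_nodes))
    g = x @ L.T
    env_lat = np.exp(g * log_sd[None, :])
    # linear upsample to the recording grid
    t_full = np.arange(n_samples) / fs
    t_coarse = np.arange(t_lat) / _LATENT_FS
    env = np.empty((n_nodes, n_samples))
    for j in range(n_nodes):
        env[j] = np.interp(t_full, t_coarse, env_lat[:, j])
    return env


def generate_recording(
    n_nodes: int,
    band: BandDefinition,
    duration_s: float,
    fs: float,
    envelope_corr: np.ndarray,
    envelope_dispersion: Optional[np.ndarray] = None,
    seed: int | np.random.SeedSequence = 0,
    epoch_length_s: float = 2.0,
    log_env_sd: float = 0.5,
    noise_floor: float = 0.05,
    meta: Optional[RecordingMeta] = None,
) -> EpochedRecording:
    """Generate one band-limited recording with correlated slow envelopes.

    ``envelope_corr`` is the latent (log-domain) target correlation; the
    attained envelope correlation after the exp transform and carrier
    modulation is smaller but strictly increasing in the target.
    ``envelope_dispersion`` multiplies the per-node log-envelope SD.
    """
    n_samples = duration_s * fs
    if abs(n_samples - round(n_samples)) > 1e-9:
        raise ValueError(f"duration_s*fs = {n_samples} is not an integer")
    n_samples = round(n_samples)
    n_ep = duration_s / epoch_length_s
    if abs(n_ep - round(n_ep)) > 1e-9:
        raise ValueError(
            f"duration {duration_s} s is not a multiple of the epoch "
            f"length {epoch_length_s} s"
        )
    band.validate_for_fs(fs)
    corr = _check_correlation(envelope_corr, n_nodes)
    disp = (
        np.ones(n_nodes)
        if envelope_dispersion is None
        else np.asarray(envelope_dispersion, dtype=float)
    )
    if disp.shape != (n_nodes,) or np.any(disp <= 0):
        raise ValueError("envelope_dispersion must be positive, one per node")

    rng = np.random.default_rng(seed)
    env = _latent_envelopes(n_nodes, n_samples, fs, corr, log_env_sd * disp, rng)
    white = rng.standard_normal((n_nodes, n_samples))
    sos = signal.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, white, axis=-1)
    carrier /= carrier.std(axis=-1, keepdims=True)
    data = env * carrier
    if noise_floor > 0:
        data = data + noise_floor * rng.standard_normal((n_nodes, n_samples))
    return EpochedRecording(
        data=data, fs=fs, epoch_length_s=epoch_length_s, meta=meta
    )


def apply_effect_spec(
    envelope_corr: np.ndarray,
    envelope_dispersion: np.ndarray,
    effect_spec: EffectSpec,
    drug: str,
    session: str,
    design: StudyDesign = StudyDesign(),
) -> tuple[np.ndarray, np.ndarray]:
    """Return (corr, dispersion) for one design cell with effects applied.

    Placebo and pre-session cells pass through unchanged.  Active post
    cells have affected-edge latent correlations multiplied by the edge
    factor (then projected back to the nearest PSD correlation matrix)
    and affected-node dispersions multiplied by the activity factors.
    """
    if drug not in design.drugs:
        raise ValueError(f"unknown drug {drug!r}")
    if session not in design.sessions:
        raise ValueError(f"unknown session {session!r}")
    corr = np.asarray(envelope_corr, dtype=float).copy()
    disp = np.asarray(envelope_dispersion, dtype=float).copy()
    if drug != effect_spec.applies_to_drug or session == "pre":
        return corr, disp
    effect_spec.validate_nodes(corr.shape[0])
    ef = _session_factor(effect_spec.edge_effect, session)
    if effect_spec.affected_edges and ef != 1.0:
        for i, j in effect_spec.affected_edges:
            corr[i, j] *= ef
            corr[j, i] = corr[i, j]
        corr = nearest_correlation_psd(corr)
    up = _session_factor(effect_spec.activity_effect_up, session)
    down = _session_factor(effect_spec.activity_effect_down, session)
    if effect_spec.affected_nodes_up:
        disp[list(effect_spec.affected_nodes_up)] *= up
    if effect_spec.affected_nodes_down:
        disp[list(effect_spec.affected_nodes_down)] *= down
    return corr, disp


def generate_template(
    effect_magnitude: np.ndarray,
    target_rho: float,
    seed: int | np.random.SeedSequence = 0,
) -> ReceptorTemplate:
    """Receptor-density map correlated with |effect| at a controlled level.

    node_values = a + b * (rho * z(|e|) + sqrt(1 - rho^2) * z(noise)),
    shifted to be nonnegative; the sample correlation with |e| converges
    to target_rho as the node count grows.
    """
    e = np.abs(np.asarray(effect_magnitude, dtype=float))
    if not np.all(np.isfinite(e)):
        raise ValueError("effect_magnitude must be finite")
    if e.std() == 0:
        raise ValueError(
            "effect_magnitude is constant; template correlation is undefined"
        )
    if not abs(target_rho) <= 1:
        raise ValueError("|target_rho| must be <= 1")
    rng = np.random.default_rng(seed)
    z_e = (e - e.mean()) / e.std()
    if abs(target_rho) == 1:
        combo = target_rho * z_e
    else:
        noise = rng.standard_normal(e.shape)
        z_n = (noise - noise.mean()) / noise.std()
        combo = target_rho * z_e + np.sqrt(1 - target_rho**2) * z_n
    values = 5.0 + 2.0 * combo
    if values.min() < 0:
        values = values - values.min()
    return ReceptorTemplate(node_values=values, target_rho=target_rho)


def base_correlation_matrix(
    n_nodes: int,
    n_blocks: int = 6,
    within: float = 0.5,
    between: float = 0.15,
) -> np.ndarray:
    """Block-modular latent correlation: contiguous communities of nodes.

    Within-block latent correlation ``within``, between-block
    ``between`` — a coarse stand-in for the modular topology of
    resting-state functional networks.
    """
    block = np.repeat(np.arange(n_blocks), int(np.ceil(n_nodes / n_blocks)))[:n_nodes]
    same = block[:, None] == block[None, :]
    corr = np.where(same, within, between)
    np.fill_diagonal(corr, 1.0)
    return _check_correlation(corr, n_nodes)


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to generate a SyntheticStudy deterministically."""

    design: StudyDesign = StudyDesign()
    n_nodes: int = 90
    duration_s: float = 300.0
    fs: float = 600.0
    epoch_length_s: float = 2.0
    carrier_band: BandDefinition = ALPHA
    log_env_sd: float = 0.5
    noise_floor: float = 0.05
    subject_corr_sd: float = 0.05
    n_blocks: int = 6
    within_block_corr: float = 0.5
    between_block_corr: float = 0.15
    effect_spec: Optional[EffectSpec] = None
    template_rho: float = 0.25
    seed: int = 0

    def resolved_effect_spec(self) -> EffectSpec:
        return (
            self.effect_spec
            if self.effect_spec is not None
            else default_effect_spec(self.n_nodes)
        )


def default_effect_spec(n_nodes: int) -> EffectSpec:
    """Default planted effects, scaled to the node count.

    Connectivity: 20 within-block edge reductions (factor 0.5) in the
    last ("posterior") block.  Activity: log-envelope dispersion up by
    1.3 on the first ("frontal") sixth of nodes and down by 0.75 on the
    last sixth.
    """
    block_size = int(np.ceil(n_nodes / 6))
    post = list(range(n_nodes - block_size, n_nodes))
    front = list(range(0, block_size))
    pairs = [
        (post[a], post[b])
        for a in range(len(post))
        for b in range(a + 1, len(post))
    ]
    n_edges = min(20, len(pairs))
    return EffectSpec(
        affected_edges=tuple(pairs[:n_edges]),
        edge_effect=0.5,
        affected_nodes_up=tuple(front),
        affected_nodes_down=tuple(post),
        activity_effect_up=1.3,
        activity_effect_down=0.75,
        applies_to_drug="active",
    )


@dataclass
class SyntheticStudy:
    """A generated study: per-cell generation parameters plus ground truth.

    Recordings are synthesised on demand (``recording``/``iter_recordings``)
    so that full-scale studies never need to be held in memory at once;
    regeneration is deterministic given the study seed.
    """

    config: StudyConfig
    effect_spec: EffectSpec
    template: ReceptorTemplate
    cell_params: dict[tuple[str, str, str], dict]
    ground_truth: dict

    @property
    def design(self) -> StudyDesign:
        return self.config.design

    @property
    def seed(self) -> int:
        return self.config.seed

    def recording(self, subject: str, drug: str, session: str) -> EpochedRecording:
        p = self.cell_params[(subject, drug, session)]
        return generate_recording(
            n_nodes=self.config.n_nodes,
            band=self.config.carrier_band,
            duration_s=self.config.duration_s,
            fs=self.config.fs,
            envelope_corr=p["corr"],
            envelope_dispersion=p["dispersion"],
            seed=np.random.SeedSequence(entropy=p["entropy"]),
            epoch_length_s=self.config.epoch_length_s,
            log_env_sd=self.config.log_env_sd,
            noise_floor=self.config.noise_floor,
            meta=RecordingMeta(subject=subject, drug=drug, session=session),
        )

    def iter_recordings(self) -> Iterator[EpochedRecording]:
        d = self.design
        for subject in d.subjects:
            for drug in d.drugs:
                for session in d.sessions:
                    yield self.recording(subject, drug, session)

    @property
    def n_recordings(self) -> int:
        return self.design.n_cells


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Build the full study: per-cell latent parameters, template, truth.

    Per-subject variability is injected as a symmetric Gaussian
    perturbation (SD ``subject_corr_sd``) of the group latent
    correlation matrix, PSD-projected; drug effects are then applied per
    cell.  The latent correlations per cell are recorded as ground truth
    alongside the planted edge/node sets.
    """
    design = config.design
    effect = config.resolved_effect_spec()
    effect.validate_nodes(config.n_nodes)
    base = base_correlation_matrix(
        config.n_nodes, config.n_blocks,
        config.within_block_corr, config.between_block_corr,
    )
    base_disp = np.ones(config.n_nodes)

    root = np.random.SeedSequence(entropy=config.seed)
    subj_seeds = root.spawn(design.n_subjects)
    template_seed, = root.spawn(1)

    cell_params: dict[tuple[str, str, str], dict] = {}
    truth_corr: dict[str, float | dict] = {}
    for si, subject in enumerate(design.subjects):
        srng = np.random.default_rng(subj_seeds[si])
        noise = srng.standard_normal((config.n_nodes, config.n_nodes))
        noise = (noise + noise.T) / np.sqrt(2.0)
        np.fill_diagonal(noise, 0.0)
        subj_corr = nearest_correlation_psd(base + config.subject_corr_sd * noise)
        for di, drug in enumerate(design.drugs):
            for ti, session in enumerate(design.sessions):
                corr, disp = apply_effect_spec(
                    subj_corr, base_disp, effect, drug, session, design
                )
                entropy = int(
                    np.random.SeedSequence(
                        entropy=config.seed,
                        spawn_key=(1 + si, di, ti),
                    ).generate_state(1, np.uint32)[0]
                )
                cell_params[(subject, drug, session)] = {
                    "corr": corr,
                    "dispersion": disp,
                    "entropy": entropy,
                }

    # ground truth: latent correlations on planted edges, per cell
    edge_truth = {}
    for (subject, drug, session), p in cell_params.items():
        edge_truth[f"{subject}/{drug}/{session}"] = [
            float(p["corr"][i, j]) for i, j in effect.affected_edges
        ]
    effect_mag = effect.node_effect_magnitude(config.n_nodes)
    template = generate_template(effect_mag, config.template_rho, template_seed)
    attained_rho = float(np.corrcoef(template.node_values, effect_mag)[0, 1])

    ground_truth = {
        "affected_edges": [list(e) for e in effect.affected_edges],
        "affected_nodes_up": list(effect.affected_nodes_up),
        "affected_nodes_down": list(effect.affected_nodes_down),
        "node_effect_magnitude": effect_mag.tolist(),
        "latent_corr_affected_edges": edge_truth,
        "template_target_rho": config.template_rho,
        "template_attained_rho": attained_rho,
    }
    return SyntheticStudy(
        config=config,
        effect_spec=effect,
        template=template,
        cell_params=cell_params,
        ground_truth=ground_truth,
    )
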