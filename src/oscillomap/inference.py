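"""Study-level statistics.

Per-feature (edge or node) drug x session repeated-measures ANOVA,
post-hoc paired t tests against the pre-drug baseline with either
sign-flip permutation omnibus (max-|t|) correction or Benjamini-
Hochberg FDR, and randomisation-based Pearson correlation of absolute
effect maps against a receptor-density template.

All permutation schemes flip/permute jointly across features so the
spatial correlation structure of the data is preserved under the null,
and all p-values use the add-one convention p = (1 + #exceedances) /
(1 + n_perm), which keeps them valid and bounded away from zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .synth import ReceptorTemplate


@dataclass
class FeaturePanel:
    """subject x drug x session x feature response array.

    Features are retained edges (connectivity) or nodes (activity);
    the panel must be complete — one finite value per design cell.
    """

    values: np.ndarray
    feature_ids: list[str]
    subjects: list[str]
    drugs: list[str]
    sessions: list[str]
    band: Optional[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (
            len(self.subjects), len(self.drugs),
            len(self.sessions), len(self.feature_ids),
        )
        if v.shape != expected:
            raise ValueError(f"panel shape {v.shape} != design {expected}")
        if not np.all(np.isfinite(v)):
            raise ValueError("panel has missing or non-finite cells")
        if len(self.subjects) < 3:
            raise ValueError("need at least 3 subjects")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class AnovaResult:
    """Per-feature F statistics for drug, session and their interaction."""

    feature_ids: list[str]
    F_drug: np.ndarray
    p_drug: np.ndarray
    df_drug: tuple[int, int]
    F_session: np.ndarray
    p_session: np.ndarray
    df_session: tuple[int, int]
    F_interaction: np.ndarray
    p_interaction: np.ndarray
    df_interaction: tuple[int, int]


@dataclass
class PosthocResult:
    """Per-feature paired-t contrast (one post session vs pre, within drug)."""

    feature_ids: list[str]
    drug: str
    session: str
    t: np.ndarray
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray
    direction: np.ndarray          # sign of t
    n_perm: int
    excluded: list[str] = field(default_factory=list)


@dataclass
class SpatialCorrResult:
    """One spatial map-vs-template correlation with omnibus-corrected p."""

    name: str
    r: float
    p_corrected: float
    n_perm: int


def _ss(x: np.ndarray) -> np.ndarray:
    return np.sum(x ** 2, axis=tuple(range(x.ndim - 1)))


def rm_anova_per_feature(panel: FeaturePanel) -> AnovaResult:
    """Two-way fully-within-subject ANOVA, vectorised over features.

    Standard partitioning: each effect is tested against its own
    effect-by-subject interaction.  For a 2 x 4 design with n subjects
    the df pairs are (1, n-1) for drug and (3, 3(n-1)) for session and
    interaction.  No sphericity correction.
    """
    y = panel.values                       # (n, D, S, F)
    n, D, S, F = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    m = y.mean(axis=(0, 1, 2))             # grand mean per feature
    m_s = y.mean(axis=(1, 2))              # (n, F) subject means
    m_d = y.mean(axis=(0, 2))              # (D, F)
    m_t = y.mean(axis=(0, 1))              # (S, F)
    m_sd = y.mean(axis=2)                  # (n, D, F)
    m_st = y.mean(axis=1)                  # (n, S, F)
    m_dt = y.mean(axis=0)                  # (D, S, F)

    ss_drug = n * S * _ss(m_d - m)
    ss_err_drug = S * _ss(m_sd - m_s[:, None, :] - m_d[None, :, :] + m)
    df_drug = (D - 1, (D - 1) * (n - 1))

    ss_sess = n * D * _ss(m_t - m)
    ss_err_sess = D * _ss(m_st - m_s[:, None, :] - m_t[None, :, :] + m)
    df_sess = (S - 1, (S - 1) * (n - 1))

    ss_int = n * _ss(m_dt - m_d[:, None, :] - m_t[None, :, :] + m)
    resid = (
        y
        - m_sd[:, :, None, :] - m_st[:, None, :, :] - m_dt[None, :, :, :]
        + m_s[:, None, None, :] + m_d[None, :, None, :] + m_t[None, None, :, :]
        - m
    )
    ss_err_int = _ss(resid)
    df_int = ((D - 1) * (S - 1), (D - 1) * (S - 1) * (n - 1))

    # SS below this (relative to the total variation) are roundoff, not effect
    ss_total = np.sum((y - m) ** 2, axis=(0, 1, 2))
    tiny = 1e-12 * (ss_total + np.finfo(float).tiny)

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        eff = np.where(ss_eff <= tiny, 0.0, ss_eff)
        err = np.where(ss_err <= tiny, 0.0, ss_err)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (eff / df_eff) / (err / df_err)
        f = np.where(err == 0, np.where(eff == 0, 0.0, np.inf), f)
        f = np.where(eff == 0, 0.0, f)
        p = stats.f.sf(f, df_eff, df_err)
        return f, p

    F_d, p_d = f_and_p(ss_drug, df_drug[0], ss_err_drug, df_drug[1])
    F_t, p_t = f_and_p(ss_sess, df_sess[0], ss_err_sess, df_sess[1])
    F_i, p_i = f_and_p(ss_int, df_int[0], ss_err_int, df_int[1])
    return AnovaResult(
        feature_ids=list(panel.feature_ids),
        F_drug=F_d, p_drug=p_d, df_drug=df_drug,
        F_session=F_t, p_session=p_t, df_session=df_sess,
        F_interaction=F_i, p_interaction=p_i, df_interaction=df_int,
    )


def paired_t(a, b) -> float:
    """Paired t statistic mean(a-b) / (SD(a-b)/sqrt(n)), sample SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences; paired t undefined")
    return float(d.mean() / (sd / np.sqrt(n)))


def _sign_flip_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for sign-flipped difference panels, vectorised.

    diffs: (n_subjects, n_features); signs: (n_perm, n_subjects) of +/-1.
    Exploits the invariance of sum(d^2) under sign flips.
    """
    n = diffs.shape[0]
    ssq = np.sum(diffs ** 2, axis=0)             # (F,)
    m = signs @ diffs / n                        # (P, F)
    var = (ssq[None, :] - n * m ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return t


def permutation_posthoc_omnibus(
    panel: FeaturePanel,
    drug: str,
    session: str,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence = 0,
    baseline: str = "pre",
) -> PosthocResult:
    """Paired t of one post session vs baseline with max-|t| omnibus FWER.

    The null is built by randomly sign-flipping each subject's
    difference vector, jointly across features; per permutation the
    maximum |t| over features is recorded, and each feature's corrected
    p is the add-one exceedance rate of that maximum against |t_obs|.
    Features with zero-variance differences are excluded (with a
    warning) and reported in ``excluded``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    di = panel.drugs.index(drug)
    si = panel.sessions.index(session)
    bi = panel.sessions.index(baseline)
    if si == bi:
        raise ValueError("contrast session equals the baseline")
    diffs = panel.values[:, di, si, :] - panel.values[:, di, bi, :]
    n = diffs.shape[0]

    sds = diffs.std(axis=0, ddof=1)
    good = sds > 0
    excluded = [f for f, ok in zip(panel.feature_ids, good) if not ok]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} degenerate feature(s) with "
            "zero-variance differences from the permutation test"
        )
    d = diffs[:, good]
    ids = [f for f, ok in zip(panel.feature_ids, good) if ok]
    if d.shape[1] == 0:
        raise ValueError("no non-degenerate features left to test")

    t_obs = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(n))
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    t_perm = _sign_flip_t(d, signs)
    abs_obs = np.abs(t_obs)
    max_t = np.max(np.abs(t_perm), axis=1)        # (P,)
    p_corr = (1 + np.sum(max_t[:, None] >= abs_obs[None, :], axis=0)) / (1 + n_perm)
    p_unc = (1 + np.sum(np.abs(t_perm) >= abs_obs[None, :], axis=0)) / (1 + n_perm)
    return PosthocResult(
        feature_ids=ids,
        drug=drug,
        session=session,
        t=t_obs,
        p_uncorrected=p_unc,
        p_corrected=np.maximum(p_corr, p_unc),
        direction=np.sign(t_obs),
        n_perm=n_perm,
        excluded=excluded,
    )


def permutation_posthoc_family(
    panel: FeaturePanel,
    contrasts: Sequence[tuple[str, str]],
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence = 0,
    baseline: str = "pre",
) -> dict[tuple[str, str], PosthocResult]:
    """Paired-t post-hocs with omnibus correction over the whole family.

    ``contrasts`` is the full post-hoc comparison family, e.g. all
    (drug, post-session) pairs.  Per permutation one sign flip is drawn
    per subject and drug and applied jointly to that drug's difference
    vectors across sessions and features, preserving both the spatial
    and the shared-baseline correlation structure; the omnibus statistic
    is the maximum |t| over every feature and every contrast.  The
    resulting corrected p-values control the family-wise error rate
    across the complete set of reported comparisons, so a study-level
    claim ("no placebo changes anywhere") inherits the nominal level.
    """
    if not contrasts:
        raise ValueError("empty contrast family")
    bi = panel.sessions.index(baseline)
    n = panel.n_subjects
    rng = np.random.default_rng(seed)
    drugs_in_family = sorted({d for d, _ in contrasts}, key=panel.drugs.index)
    signs = {
        d: rng.choice((-1.0, 1.0), size=(n_perm, n)) for d in drugs_in_family
    }

    per_contrast: dict[tuple[str, str], dict] = {}
    max_t = np.zeros(n_perm)
    for d, s in contrasts:
        di = panel.drugs.index(d)
        si = panel.sessions.index(s)
        if si == bi:
            raise ValueError("contrast session equals the baseline")
        diffs = panel.values[:, di, si, :] - panel.values[:, di, bi, :]
        sds = diffs.std(axis=0, ddof=1)
        good = sds > 0
        excluded = [f for f, ok in zip(panel.feature_ids, good) if not ok]
        if excluded:
            warnings.warn(
                f"excluding {len(excluded)} degenerate feature(s) from "
                f"contrast {d}/{s}"
            )
        dmat = diffs[:, good]
        if dmat.shape[1] == 0:
            raise ValueError(f"no testable features in contrast {d}/{s}")
        t_obs = dmat.mean(axis=0) / (dmat.std(axis=0, ddof=1) / np.sqrt(n))
        t_perm = np.abs(_sign_flip_t(dmat, signs[d]))
        np.maximum(max_t, t_perm.max(axis=1), out=max_t)
        per_contrast[(d, s)] = {
            "ids": [f for f, ok in zip(panel.feature_ids, good) if ok],
            "t_obs": t_obs,
            "t_perm": t_perm,
            "excluded": excluded,
        }

    results: dict[tuple[str, str], PosthocResult] = {}
    for (d, s), c in per_contrast.items():
        abs_obs = np.abs(c["t_obs"])
        p_corr = (1 + np.sum(max_t[:, None] >= abs_obs[None, :], axis=0)) / (1 + n_perm)
        p_unc = (1 + np.sum(c["t_perm"] >= abs_obs[None, :], axis=0)) / (1 + n_perm)
        results[(d, s)] = PosthocResult(
            feature_ids=c["ids"],
            drug=d,
            session=s,
            t=c["t_obs"],
            p_uncorrected=p_unc,
            p_corrected=np.maximum(p_corr, p_unc),
            direction=np.sign(c["t_obs"]),
            n_perm=n_perm,
            excluded=c["excluded"],
        )
    return results


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted p), input order.

    Reject all hypotheses with rank <= max{i : p_(i) <= i*q/m}; adjusted
    p-values are the cumulative minimum (from the largest rank down) of
    m*p_(i)/i, clipped to 1.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(ranked <= thresh)
    k = passing[-1] + 1 if passing.size else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    adj_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject = np.zeros(m, dtype=bool)
    adjusted = np.zeros(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return reject, adjusted


def spatial_correlation_test(
    effect_maps: dict[str, np.ndarray],
    template: ReceptorTemplate | np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence = 0,
) -> list[SpatialCorrResult]:
    """Randomisation Pearson correlation of |effect| maps vs a template.

    ``effect_maps`` is the declared comparison family (e.g. one absolute
    paired-t map per post session); the null permutes the template's
    node assignment, and omnibus correction uses the per-permutation
    maximum |r| over the family.
    """
    tv = template.node_values if isinstance(template, ReceptorTemplate) else np.asarray(template, dtype=float)
    if not effect_maps:
        raise ValueError("empty comparison family")
    maps = {k: np.abs(np.asarray(v, dtype=float)) for k, v in effect_maps.items()}
    n_nodes = tv.size
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    if tv.std() == 0:
        raise ValueError("constant template; correlation undefined")
    for k, v in maps.items():
        if v.shape != (n_nodes,):
            raise ValueError(f"map {k!r} not on the template's node set")
        if v.std() == 0:
            raise ValueError(f"constant effect map {k!r}; correlation undefined")

    names = list(maps)
    M = np.stack([maps[k] for k in names])                 # (C, N)
    Mz = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
    tz = (tv - tv.mean()) / tv.std()
    r_obs = Mz @ tz / n_nodes                              # (C,)

    rng = np.random.default_rng(seed)
    max_r = np.empty(n_perm)
    for p_i in range(n_perm):
        perm = rng.permutation(n_nodes)
        r_null = Mz @ tz[perm] / n_nodes
        max_r[p_i] = np.max(np.abs(r_null))
    results = []
    for ci, name in enumerate(names):
        p_corr = (1 + np.sum(max_r >= abs(r_obs[ci]))) / (1 + n_perm)
        results.append(
            SpatialCorrResult(
                name=name, r=float(r_obs[ci]),
                p_corrected=float(p_corr), n_perm=n_perm,
            )
        )
    return results
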