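"""Connectivity normalization chain.

Raw envelope correlations are made comparable across recordings in three
steps:

1. Fisher z (atanh) variance stabilisation.
2. Surrogate normalisation: each edge's z is divided by the SD of a
   null distribution built by circularly shifting one member of the
   pair, which preserves each envelope's autocorrelation while
   destroying the cross-correlation.  This corrects for the effective
   temporal degrees of freedom of slow, autocorrelated envelopes.
3. Session standardisation ("noise-peak" z-scoring): a Gaussian is
   fitted to the central mode of the value distribution of one
   recording's matrix, and its mu/sigma are used to z-score the whole
   matrix.  Fitting only the noise peak keeps the estimate robust to
   the heavy tail of genuinely coupled edges, and removes global
   session confounds (SNR, head position and the like).

Finally, mean-rank pruning keeps only the edges consistently strong
across every recording in the study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .recording import ConnectivityMatrix, EnvelopeSet, upper_triangle_indices
from .envelope import aec_matrix


class NoisePeakFitError(RuntimeError):
    """Gaussian noise-peak fit failed; carries the initial robust estimates."""

    def __init__(self, message: str, robust_mu: float, robust_sigma: float):
        super().__init__(
            f"{message} (robust fallback estimates: mu={robust_mu:.6g}, "
            f"sigma={robust_sigma:.6g})"
        )
        self.robust_mu = robust_mu
        self.robust_sigma = robust_sigma


@dataclass(frozen=True)
class NoisePeakFit:
    """Location/scale of the Gaussian fitted to a distribution's noise peak."""

    mu: float
    sigma: float
    n_used: int

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("fitted sigma must be positive")
        if self.n_used < 10:
            raise ValueError("noise-peak fit used fewer than 10 values")


@dataclass(frozen=True)
class EdgeMask:
    """Symmetric boolean edge-retention mask with a false diagonal."""

    mask: np.ndarray
    retain_fraction: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mask must be square")
        if np.any(np.diag(m)):
            raise ValueError("mask diagonal must be false")
        if not np.array_equal(m, m.T):
            raise ValueError("mask must be symmetric")
        object.__setattr__(self, "mask", m)

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum()) // 2

    def edge_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) arrays of retained edges with i < j, lexicographic order."""
        iu = upper_triangle_indices(self.mask.shape[0])
        keep = self.mask[iu]
        return iu[0][keep], iu[1][keep]


def fisher_z(r):
    """Variance-stabilising Fisher z transform, elementwise.

    NaNs (the matrix diagonal) are preserved; |r| >= 1 raises.
    """
    arr = np.asarray(r, dtype=float)
    finite = np.isfinite(arr)
    if np.any(np.abs(arr[finite]) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.full_like(arr, np.nan)
    out[finite] = np.arctanh(arr[finite])
    if np.isscalar(r) or arr.ndim == 0:
        return float(out)
    return out


def fisher_z_matrix(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher-z a stage-'r' connectivity matrix."""
    if cm.stage != "r":
        raise ValueError(f"expected stage 'r', got {cm.stage!r}")
    return cm.with_values(fisher_z(cm.values), stage="fisher_z")


def surrogate_normalize(
    env_1s: EnvelopeSet,
    n_surrogates: int = 100,
    seed: int | np.random.SeedSequence = 0,
    min_shift: int = 5,
    subtract_null_mean: bool = False,
) -> ConnectivityMatrix:
    """Variance-normalised Fisher z via circular-shift surrogates.

    For each edge, the observed Fisher z is divided by the SD of
    ``n_surrogates`` null Fisher-z values, each obtained by circularly
    shifting one member of the pair by a uniform random offset of at
    least ``min_shift`` samples.  Deterministic given ``seed``.
    """
    if n_surrogates < 50:
        raise ValueError("need at least 50 surrogates for a stable null SD")
    X = env_1s.env
    n, T = X.shape
    if T < 10:
        raise ValueError("need at least 10 envelope samples")
    if T <= 2 * min_shift:
        raise ValueError(
            f"envelope too short ({T} samples) for shifts of >= {min_shift}"
        )
    observed = aec_matrix(env_1s)
    # clip before atanh so perfectly coupled envelopes yield a huge finite z
    z_obs = np.arctanh(np.clip(observed.values, -1 + 1e-12, 1 - 1e-12))

    # row-standardize once; circular shifts preserve mean/SD
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Xs = (X - mu) / sd

    rng = np.random.default_rng(seed)
    iu = upper_triangle_indices(n)
    null_z = np.empty((n_surrogates, iu[0].size))
    col = np.arange(T)
    for k in range(n_surrogates):
        offsets = rng.integers(min_shift, T - min_shift + 1, size=n)
        idx = (col[None, :] - offsets[:, None]) % T
        Ys = np.take_along_axis(Xs, idx, axis=1)
        # corr(x_i, shift(x_j)): shift applied to the second (j) member
        c = (Xs @ Ys.T) / T
        np.clip(c, -0.999999, 0.999999, out=c)
        null_z[k] = np.arctanh(c[iu])
    null_sd = null_z.std(axis=0, ddof=1)
    if np.any(null_sd == 0):
        bad = int(np.flatnonzero(null_sd == 0)[0])
        raise ValueError(f"degenerate (zero-SD) surrogate null for edge {bad}")
    null_mu = null_z.mean(axis=0) if subtract_null_mean else 0.0

    out = np.full((n, n), np.nan)
    normalized = (z_obs[iu] - null_mu) / null_sd
    out[iu] = normalized
    out[(iu[1], iu[0])] = normalized
    return observed.with_values(out, stage="z_surrogate")


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_window(values: np.ndarray, center: float, width: float):
    sel = values[(values >= center - width) & (values <= center + width)]
    if sel.size < 10:
        raise ValueError(
            f"only {sel.size} values inside the fitting window"
        )
    # Freedman-Diaconis bin width on the windowed values
    q75, q25 = np.percentile(sel, [75, 25])
    iqr = q75 - q25
    bw = 2 * iqr / sel.size ** (1 / 3) if iqr > 0 else None
    span = sel.max() - sel.min()
    if bw is None or bw <= 0 or span <= 0:
        n_bins = 10
    else:
        n_bins = max(5, int(np.ceil(span / bw)))
    counts, edges = np.histogram(sel, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    p0 = (float(counts.max()), center, width)
    # bounds keep the fit on the central mode: sigma cannot collapse to a
    # single bin nor balloon past the window
    bounds = (
        [0.0, center - width, width / 20.0],
        [10.0 * counts.max() + 1.0, center + width, 5.0 * width],
    )
    popt, _ = optimize.curve_fit(
        _gauss, centers, counts, p0=p0, bounds=bounds, maxfev=10000
    )
    return float(popt[1]), float(abs(popt[2])), int(sel.size)


def fit_noise_peak(values) -> NoisePeakFit:
    """Fit a Gaussian to the noise peak (+/- 1 SD) of a value distribution.

    Robust seeding (median, 1.4826*MAD), a least-squares Gaussian fit to
    the Freedman-Diaconis histogram within the window, then one refit
    with the window re-centred on the fitted mu +/- fitted sigma.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 50:
        raise ValueError(f"need at least 50 finite values, got {v.size}")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    sigma0 = 1.4826 * mad
    if sigma0 == 0:
        sigma0 = float(v.std())
    if sigma0 == 0:
        raise ValueError("all values equal; noise peak undefined")
    try:
        mu1, s1, _ = _fit_window(v, med, sigma0)
        mu2, s2, n_used = _fit_window(v, mu1, s1)
    except (ValueError, RuntimeError) as exc:
        raise NoisePeakFitError(
            f"Gaussian noise-peak fit failed: {exc}", med, sigma0
        ) from exc
    if not (np.isfinite(mu2) and np.isfinite(s2) and s2 > 0):
        raise NoisePeakFitError(
            "Gaussian noise-peak fit did not converge to a positive sigma",
            med, sigma0,
        )
    return NoisePeakFit(mu=mu2, sigma=s2, n_used=n_used)


def zscore_by_noise_peak(values, fit: NoisePeakFit):
    """(x - mu) / sigma elementwise; NaNs pass through."""
    arr = np.asarray(values, dtype=float)
    return (arr - fit.mu) / fit.sigma


def standardize_session(cm: ConnectivityMatrix) -> tuple[ConnectivityMatrix, NoisePeakFit]:
    """Noise-peak z-score one recording's connectivity matrix."""
    fit = fit_noise_peak(cm.upper_values())
    return cm.with_values(zscore_by_noise_peak(cm.values, fit), stage="z_session"), fit


def mean_rank_mask(
    matrices: Sequence[ConnectivityMatrix] | Sequence[np.ndarray],
    retain_fraction: float,
) -> EdgeMask:
    """Retain the edges with the highest mean rank across all matrices.

    Within each matrix the unique edges are ranked ascending by value
    (ties get average ranks); ranks are averaged across matrices, and
    the ceil(retain_fraction * n_edges) edges with the highest mean rank
    are kept.  Ties at the cutoff are broken deterministically by (i, j)
    lexicographic order.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    arrays = [
        m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
        for m in matrices
    ]
    if not arrays:
        raise ValueError("need at least one matrix")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all matrices must share one shape")
    n = shape[0]
    iu = upper_triangle_indices(n)
    ranks = np.zeros(iu[0].size)
    for a in arrays:
        ranks += stats.rankdata(a[iu])
    ranks /= len(arrays)
    n_keep = int(np.ceil(retain_fraction * iu[0].size))
    # sort by (-mean rank, i, j); lexsort keys are last-key-primary
    order = np.lexsort((iu[1], iu[0], -ranks))
    keep = order[:n_keep]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[0][keep], iu[1][keep]] = True
    mask |= mask.T
    return EdgeMask(mask=mask, retain_fraction=retain_fraction)
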