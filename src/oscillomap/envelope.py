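"""From epoched node time series to leakage-corrected 1-s amplitude envelopes.

The fixed pipeline order is: region reduction (if starting from voxels)
-> per-epoch band-pass -> epoch concatenation -> symmetric
orthogonalization (connectivity path only) -> Hilbert envelope -> 1-s
window-mean downsampling -> median filtering -> envelope correlation.

Band-pass filtering uses a zero-phase forward-backward 4th-order
Butterworth, applied per epoch so each epoch is filtered on its own
support; the Hilbert transform is taken over the concatenated series.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .bands import BandDefinition
from .recording import (
    ConnectivityMatrix,
    EnvelopeSet,
    EpochedRecording,
    upper_triangle_indices,
)


def select_region_representatives(
    voxel_data: np.ndarray,
    region_of_voxel: np.ndarray,
    fs: float,
    epoch_length_s: float = 2.0,
    region_labels: Optional[list[str]] = None,
    meta=None,
) -> EpochedRecording:
    """Reduce voxel x time data to one representative voxel per region.

    For each region the voxel with the largest temporal standard
    deviation is selected; ties are broken by the lowest voxel index.
    ``region_of_voxel`` maps each voxel row to an integer region id;
    regions are emitted in sorted id order.
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    if not np.all(np.isfinite(voxel_data)):
        raise ValueError("voxel data contains non-finite values")
    region_of_voxel = np.asarray(region_of_voxel)
    if region_of_voxel.shape != (voxel_data.shape[0],):
        raise ValueError("region_of_voxel must have one entry per voxel row")

    regions = np.unique(region_of_voxel)
    sds = voxel_data.std(axis=1)
    rows = []
    for r in regions:
        idx = np.flatnonzero(region_of_voxel == r)
        if idx.size == 0:  # unreachable via np.unique; guards callers passing lists
            raise ValueError(f"region {r!r} has no voxels")
        # argmax returns the first maximum -> lowest-index tie-break for free
        best = idx[np.argmax(sds[idx])]
        rows.append(voxel_data[best])
    labels = region_labels if region_labels is not None else [str(r) for r in regions]
    return EpochedRecording(
        data=np.asarray(rows),
        fs=fs,
        epoch_length_s=epoch_length_s,
        node_labels=labels,
        meta=meta,
    )


def _band_sos(band: BandDefinition, fs: float, order: int = 4):
    band.validate_for_fs(fs)
    return signal.butter(
        order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(rec: EpochedRecording, band: BandDefinition, order: int = 4) -> EpochedRecording:
    """Zero-phase band-pass filter each node within each epoch."""
    sos = _band_sos(band, rec.fs, order)
    epochs = rec.epoch_view()
    filtered = signal.sosfiltfilt(sos, epochs, axis=-1)
    return rec.with_data(filtered.reshape(rec.n_nodes, rec.n_samples))


def concatenate_epochs(rec: EpochedRecording) -> np.ndarray:
    """Join epochs in temporal order into a (n_nodes, n_samples) array.

    The epoched layout is already stored contiguously in time, so this
    is a copy of the data; it exists to mark the pipeline stage where
    epoch boundaries stop mattering.
    """
    return rec.data.copy()


def symmetric_orthogonalize(
    data: np.ndarray, tol: float = 1e-12, max_iter: int = 60
) -> np.ndarray:
    """Closest (Frobenius) set of mutually orthogonal rows to ``data``.

    Finds ``P = diag(rho) @ U`` with orthonormal rows ``U`` and free
    per-row scales ``rho`` minimising ``||data - P||_F``, by alternating
    a polar (Procrustes) step for ``U`` with the closed-form update
    ``rho_i = <data_i, U_i>``.  All pairwise zero-lag inner products of
    the output rows vanish, while each row stays as close as possible to
    its input — the standard multivariate leakage correction for
    source-reconstructed electrophysiology.

    Raises ValueError on rank-deficient input (fewer effective
    dimensions than rows means no orthogonal set exists nearby).
    """
    D = np.asarray(data, dtype=float)
    n, t = D.shape
    if t < n:
        raise ValueError(
            f"need at least as many time points ({t}) as nodes ({n}) "
            "to orthogonalize"
        )
    # economy factorization D = A @ B with B (n x t) orthonormal rows:
    # all iterations then run in n x n space.
    G = D @ D.T
    w, V = np.linalg.eigh(G)
    if w[-1] <= 0 or w[0] < w[-1] * 1e-12:
        bad = int(np.argmin(w))
        raise ValueError(
            f"input is rank deficient (eigenvalue {w[bad]:.3e} of the Gram "
            f"matrix is negligible vs {w[-1]:.3e}); symmetric "
            "orthogonalization requires full row rank"
        )
    s = np.sqrt(w)
    B = (V / s).T @ D          # orthonormal rows
    A = V * s                  # D == A @ B up to rounding

    rho = np.linalg.norm(D, axis=1)
    last = np.inf
    for _ in range(max_iter):
        # Procrustes step: the orthogonal U maximising tr(U^T diag(rho) A)
        # is W Z^T from the SVD of diag(rho) @ A.
        M = (A.T * rho).T      # diag(rho) @ A
        W, _, Zt = np.linalg.svd(M)
        U = W @ Zt             # orthogonal n x n
        # rho update: rho_i = <A_i, U_i> (inner products in reduced space)
        rho_new = np.einsum("ij,ij->i", A, U)
        if np.any(rho_new <= 0):
            raise ValueError(
                "symmetric orthogonalization failed: a row collapsed to "
                "nonpositive scale (input rows may be anti-aligned)"
            )
        obj = float(np.sum((A - (U.T * rho_new).T) ** 2))
        if abs(last - obj) <= tol * max(1.0, obj):
            rho = rho_new
            break
        rho, last = rho_new, obj
    return (U.T * rho).T @ B


def hilbert_envelope(data: np.ndarray) -> np.ndarray:
    """Per-node magnitude of the analytic signal (Hilbert envelope)."""
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("input contains non-finite values")
    return np.abs(signal.hilbert(data, axis=-1))


def downsample_envelope(
    env: np.ndarray,
    fs: float,
    band: BandDefinition,
    node_labels=None,
    meta=None,
) -> EnvelopeSet:
    """Downsample a full-rate envelope to 1-s resolution by window means.

    Non-overlapping 1-s windows; a trailing partial window is discarded.
    """
    env = np.asarray(env, dtype=float)
    win = round(fs)
    n_win = env.shape[1] // win
    if n_win < 1:
        raise ValueError(
            f"recording shorter than 1 s ({env.shape[1]} samples at {fs} Hz)"
        )
    trimmed = env[:, : n_win * win]
    means = trimmed.reshape(env.shape[0], n_win, win).mean(axis=2)
    return EnvelopeSet(env=means, band=band, node_labels=node_labels, meta=meta)


def median_filter_envelope(env_1s: EnvelopeSet, k: int = 3) -> EnvelopeSet:
    """Sliding-median filter (reflected boundaries) to remove envelope spikes."""
    if k % 2 == 0:
        raise ValueError(f"median filter window must be odd, got {k}")
    if k < 1 or k > env_1s.n_samples:
        raise ValueError(
            f"median filter window {k} outside [1, {env_1s.n_samples}]"
        )
    if k == 1:
        return env_1s
    filtered = ndimage.median_filter(env_1s.env, size=(1, k), mode="reflect")
    return EnvelopeSet(
        env=filtered,
        band=env_1s.band,
        node_labels=env_1s.node_labels,
        meta=env_1s.meta,
    )


def aec_matrix(env_1s: EnvelopeSet) -> ConnectivityMatrix:
    """Amplitude envelope correlation: zero-lag Pearson r per node pair.

    Only the n(n-1)/2 unique unordered pairs are distinct; they are
    mirrored into a symmetric matrix with a NaN diagonal.
    """
    env = env_1s.env
    if env.shape[1] < 3:
        raise ValueError("need at least 3 envelope samples to correlate")
    sd = env.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [env_1s.node_labels[i] for i in dead]
        raise ValueError(f"zero-variance envelope for node(s) {names}")
    r = np.corrcoef(env)
    np.fill_diagonal(r, np.nan)
    # enforce exact symmetry against floating point asymmetries
    iu = upper_triangle_indices(env.shape[0])
    sym = np.full_like(r, np.nan)
    sym[iu] = r[iu]
    sym[(iu[1], iu[0])] = r[iu]
    return ConnectivityMatrix(
        values=sym,
        stage="r",
        band=env_1s.band,
        node_labels=env_1s.node_labels,
        meta=env_1s.meta,
    )


def envelopes_for_recording(
    rec: EpochedRecording,
    band: BandDefinition,
    orthogonalize: bool = True,
    median_k: int = 3,
) -> EnvelopeSet:
    """Run the envelope portion of the pipeline for one recording and band.

    band-pass (per epoch) -> concatenate -> [symmetric orthogonalization]
    -> Hilbert envelope -> 1-s window means -> median filter.  The
    connectivity path orthogonalizes; the activity path does not.
    """
    filtered = bandpass(rec, band)
    series = concatenate_epochs(filtered)
    if orthogonalize:
        series = symmetric_orthogonalize(series)
    env = hilbert_envelope(series)
    env_1s = downsample_envelope(
        env, rec.fs, band, node_labels=rec.node_labels, meta=rec.meta
    )
    return median_filter_envelope(env_1s, k=median_k)
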