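"""Envelope-variability "activity" mapping.

Activity at a node is the temporal coefficient of variation (CoV) of
its band-limited amplitude envelope: envelope SD divided by envelope
mean.  Being a ratio, it is insensitive to the per-session gain
confounds that make raw source power incomparable across sessions.
Maps are optionally session-standardised with the same noise-peak
Gaussian z-scoring used for connectivity.

The activity path shares the envelope code with the connectivity path
but skips symmetric orthogonalization by default.
"""

from __future__ import annotations

import numpy as np

from .bands import BandDefinition
from .envelope import envelopes_for_recording
from .recording import ActivityMap, EnvelopeSet, EpochedRecording
from .standardize import NoisePeakFit, fit_noise_peak, zscore_by_noise_peak


def coefficient_of_variation(env: np.ndarray) -> float:
    """Sample SD (n-1 denominator) over mean of a single-node envelope."""
    x = np.asarray(env, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 envelope samples")
    m = x.mean()
    if not m > 0:
        raise ValueError(f"envelope mean must be positive, got {m}")
    return float(x.std(ddof=1) / m)


def activity_from_envelopes(env_1s: EnvelopeSet) -> ActivityMap:
    """Per-node CoV of an existing 1-s envelope set."""
    values = np.array([coefficient_of_variation(row) for row in env_1s.env])
    return ActivityMap(
        values=values,
        band=env_1s.band,
        stage="cov",
        node_labels=env_1s.node_labels,
        meta=env_1s.meta,
    )


def activity_map(
    rec: EpochedRecording,
    band: BandDefinition,
    median_k: int = 3,
    orthogonalize: bool = False,
) -> ActivityMap:
    """Band-limited envelope CoV per node for one recording.

    Runs band-pass -> concatenate -> Hilbert envelope -> 1-s downsample
    -> median filter, then CoV per node.  No orthogonalization by
    default: leakage correction is a connectivity concern and would
    redistribute variance across nodes here.
    """
    env_1s = envelopes_for_recording(
        rec, band, orthogonalize=orthogonalize, median_k=median_k
    )
    return activity_from_envelopes(env_1s)


def standardize_activity(amap: ActivityMap) -> tuple[ActivityMap, NoisePeakFit]:
    """Noise-peak z-score an activity map across its nodes."""
    if amap.n_nodes < 50:
        raise ValueError(
            f"need >= 50 nodes for a stable noise-peak fit, got {amap.n_nodes}"
        )
    fit = fit_noise_peak(amap.values)
    z = zscore_by_noise_peak(amap.values, fit)
    return (
        ActivityMap(
            values=z,
            band=amap.band,
            stage="z_session",
            node_labels=amap.node_labels,
            meta=amap.meta,
        ),
        fit,
    )
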