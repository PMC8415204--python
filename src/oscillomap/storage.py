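"""File formats: HDF5 study containers, tidy TSV tables, JSON reports.

A study is written as one HDF5 file with datasets keyed
``recordings/<subject>/<drug>/<session>`` plus a JSON sidecar
(``<path>.json``) carrying the design, bands, seed, effect spec and
ground truth.  Result tables are tab-separated with a deterministic
column order, rows sorted, and floats at 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import h5py
import numpy as np
import pandas as pd

from .config import PipelineConfig, config_to_dict
from .recording import EpochedRecording, RecordingMeta
from .synth import ReceptorTemplate, SyntheticStudy

FLOAT_FORMAT = "%.6g"


def write_study_h5(
    study: SyntheticStudy, path: str | Path, materialize: bool = True
) -> Path:
    """Write a study container; the JSON sidecar goes to ``<path>.json``.

    With ``materialize=False`` only the per-cell latent parameters and
    metadata are stored (recordings are regenerable from the seed).
    """
    path = Path(path)
    cfg = study.config
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = cfg.fs
        f.attrs["epoch_length_s"] = cfg.epoch_length_s
        f.attrs["n_nodes"] = cfg.n_nodes
        f.attrs["duration_s"] = cfg.duration_s
        f.attrs["seed"] = cfg.seed
        f.attrs["carrier_band"] = cfg.carrier_band.name
        tgrp = f.create_group("template")
        tgrp.create_dataset("node_values", data=study.template.node_values)
        tgrp.attrs["target_rho"] = study.template.target_rho
        lat = f.create_group("latent")
        for (subject, drug, session), p in study.cell_params.items():
            g = lat.create_group(f"{subject}/{drug}/{session}")
            g.create_dataset("corr", data=p["corr"])
            g.create_dataset("dispersion", data=p["dispersion"])
            g.attrs["entropy"] = p["entropy"]
        if materialize:
            rgrp = f.create_group("recordings")
            for rec in study.iter_recordings():
                m = rec.meta
                rgrp.create_dataset(
                    f"{m.subject}/{m.drug}/{m.session}", data=rec.data
                )
    sidecar = {
        "config": config_to_dict(
            PipelineConfig(study=cfg, seed=cfg.seed)
        ),
        "ground_truth": study.ground_truth,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_recordings_h5(path: str | Path) -> Iterable[EpochedRecording]:
    """Iterate materialized recordings from a study HDF5 container."""
    with h5py.File(path, "r") as f:
        if "recordings" not in f:
            raise ValueError(f"{path} has no materialized recordings")
        fs = float(f.attrs["fs"])
        epoch = float(f.attrs["epoch_length_s"])
        for subject in sorted(f["recordings"]):
            for drug in sorted(f["recordings"][subject]):
                for session in sorted(f["recordings"][subject][drug]):
                    yield EpochedRecording(
                        data=f["recordings"][subject][drug][session][()],
                        fs=fs,
                        epoch_length_s=epoch,
                        meta=RecordingMeta(subject, drug, session),
                    )


class LoadedStudy:
    """Study adapter over a materialized HDF5 container + JSON sidecar.

    Presents the same surface the pipeline needs from a SyntheticStudy
    (design, config, template, effect spec, recording iteration) but
    streams recordings from disk instead of regenerating them.
    """

    def __init__(self, path: str | Path):
        from .config import config_from_dict

        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"study file {path} does not exist")
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"study sidecar {sidecar} does not exist")
        meta = json.loads(sidecar.read_text())
        pipeline_cfg = config_from_dict(meta["config"])
        self.path = path
        self.config = pipeline_cfg.study
        self.effect_spec = self.config.resolved_effect_spec()
        self.ground_truth = meta.get("ground_truth", {})
        self.template = load_template_h5(path)
        with h5py.File(path, "r") as f:
            if "recordings" not in f:
                raise ValueError(
                    f"{path} has no materialized recordings; regenerate with "
                    "materialize=True or analyse from the config instead"
                )

    @property
    def design(self):
        return self.config.design

    @property
    def n_recordings(self) -> int:
        return self.design.n_cells

    def recording(self, subject: str, drug: str, session: str) -> EpochedRecording:
        with h5py.File(self.path, "r") as f:
            return EpochedRecording(
                data=f["recordings"][subject][drug][session][()],
                fs=float(f.attrs["fs"]),
                epoch_length_s=float(f.attrs["epoch_length_s"]),
                meta=RecordingMeta(subject, drug, session),
            )

    def iter_recordings(self) -> Iterable[EpochedRecording]:
        d = self.design
        for subject in d.subjects:
            for drug in d.drugs:
                for session in d.sessions:
                    yield self.recording(subject, drug, session)


def load_template_h5(path: str | Path) -> ReceptorTemplate:
    with h5py.File(path, "r") as f:
        return ReceptorTemplate(
            node_values=f["template/node_values"][()],
            target_rho=float(f["template"].attrs["target_rho"]),
        )


def write_template_tsv(template: ReceptorTemplate, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "node": np.arange(template.n_nodes),
            "value": template.node_values,
        }
    )
    return write_table(df, path, sort_by=["node"])


def read_template_tsv(path: str | Path) -> ReceptorTemplate:
    """Node->value TSV; target_rho is unknown for external maps (stored as 0)."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("node")
    return ReceptorTemplate(node_values=df["value"].to_numpy(), target_rho=0.0)


def write_table(df: pd.DataFrame, path: str | Path, sort_by=None) -> Path:
    """Deterministic TSV: fixed column order as given, sorted rows, %.6g."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.sort_values(list(sort_by), kind="stable") if sort_by else df
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_edge_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Long-format edge table sorted by (band, subject, drug, session, i, j)."""
    keys = [
        k for k in ("band", "subject", "drug", "session", "stage", "node_i", "node_j")
        if k in df.columns
    ]
    return write_table(df, path, sort_by=keys)


def write_map_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Long-format per-node table sorted by (band, subject, drug, session, node)."""
    keys = [
        k for k in ("band", "subject", "drug", "session", "stage", "node")
        if k in df.columns
    ]
    return write_table(df, path, sort_by=keys)


def edges_long_format(matrix_values: np.ndarray, **labels) -> pd.DataFrame:
    """Upper-triangle (i<j) long format of a symmetric matrix with labels."""
    n = matrix_values.shape[0]
    iu = np.triu_indices(n, k=1)
    df = pd.DataFrame(
        {"node_i": iu[0], "node_j": iu[1], "value": matrix_values[iu]}
    )
    for k, v in labels.items():
        df[k] = v
    return df


def write_map_nifti(
    values: np.ndarray,
    voxel_indices: np.ndarray,
    path: str | Path,
    shape: Optional[tuple[int, int, int]] = None,
    affine: Optional[np.ndarray] = None,
) -> Path:
    """Optional NIfTI export of a per-node map given node->voxel indices.

    ``voxel_indices`` is (n_nodes, 3) integer (i, j, k) coordinates;
    unassigned voxels are NaN.  Requires nibabel.
    """
    import nibabel as nib

    values = np.asarray(values, dtype=float)
    idx = np.asarray(voxel_indices, dtype=int)
    if idx.shape != (values.size, 3):
        raise ValueError("voxel_indices must be (n_nodes, 3)")
    if shape is None:
        shape = tuple(idx.max(axis=0) + 1)
    vol = np.full(shape, np.nan, dtype=np.float32)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    img = nib.Nifti1Image(vol, affine if affine is not None else np.eye(4))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_json_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
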