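"""File I/O: GIFTI surfaces, TSV label tables, TSV time series with JSON
sidecars, TSV matrices, BIDS-style events tables, and run manifests.

All numeric payloads round-trip at double precision.  TSV with a JSON
sidecar is the lingua franca; GIFTI is used for surfaces and per-vertex
maps.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from nibabel import gifti
from nibabel.nifti1 import intent_codes

from .topography import DistanceField
from .types import ParcelLabeling, ParcelTimeSeries, SurfaceMesh, TaskDesign

__all__ = [
    "write_surface", "read_surface",
    "write_labels", "read_labels",
    "write_timeseries", "read_timeseries",
    "write_matrix", "read_matrix",
    "write_events", "read_events",
    "write_vertex_map", "read_vertex_map",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# surfaces (GIFTI + JSON landmark sidecar)


def write_surface(mesh: SurfaceMesh, path: str | Path) -> Path:
    path = Path(path)
    # GIFTI restricts arrays to float32/int32; coordinates in mm lose
    # nothing material at single precision
    coords = gifti.GiftiDataArray(
        mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET",
        datatype="NIFTI_TYPE_FLOAT32",
    )
    tris = gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE",
        datatype="NIFTI_TYPE_INT32",
    )
    img = gifti.GiftiImage(darrays=[coords, tris])
    nib.save(img, str(path))
    sidecar = path.with_suffix(path.suffix + ".landmarks.json")
    with open(sidecar, "w") as fh:
        json.dump({k: v.tolist() for k, v in mesh.landmark_sets.items()}, fh)
    return path


def read_surface(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    img = nib.load(str(path))
    coords = tris = None
    for da in img.darrays:
        if da.intent == intent_codes.code["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(da.data, dtype=float)
        elif da.intent == intent_codes.code["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(da.data, dtype=np.int64)
    if coords is None or tris is None:
        raise ValueError(f"{path}: not a GIFTI surface (missing pointset/triangles)")
    landmarks = {}
    sidecar = path.with_suffix(path.suffix + ".landmarks.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            landmarks = {k: np.asarray(v, dtype=np.int64) for k, v in json.load(fh).items()}
    return SurfaceMesh(coords, tris, landmarks)


def write_vertex_map(values: np.ndarray | DistanceField, path: str | Path) -> Path:
    """Per-vertex scalar map as a GIFTI functional file."""
    if isinstance(values, DistanceField):
        values = values.values
    path = Path(path)
    da = gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE",
        datatype="NIFTI_TYPE_FLOAT32",
    )
    nib.save(gifti.GiftiImage(darrays=[da]), str(path))
    return path


def read_vertex_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(Path(path)))
    if not img.darrays:
        raise ValueError(f"{path}: empty GIFTI file")
    return np.asarray(img.darrays[0].data, dtype=float)


# ---------------------------------------------------------------------------
# labels (two TSVs)


def write_labels(labeling: ParcelLabeling, prefix: str | Path) -> tuple[Path, Path]:
    """`<prefix>_vertices.tsv` (vertex_id, parcel_id) and
    `<prefix>_parcels.tsv` (parcel_id, network_id, network_name)."""
    prefix = Path(prefix)
    vpath = prefix.parent / (prefix.name + "_vertices.tsv")
    ppath = prefix.parent / (prefix.name + "_parcels.tsv")
    pd.DataFrame(
        {"vertex_id": np.arange(labeling.n_vertices), "parcel_id": labeling.vertex_parcel}
    ).to_csv(vpath, sep="\t", index=False)
    pd.DataFrame(
        {
            "parcel_id": np.arange(1, labeling.n_parcels + 1),
            "network_id": labeling.parcel_network,
            "network_name": [
                labeling.network_names[k - 1] for k in labeling.parcel_network
            ],
        }
    ).to_csv(ppath, sep="\t", index=False)
    return vpath, ppath


def read_labels(prefix: str | Path, n_vertices: int | None = None) -> ParcelLabeling:
    prefix = Path(prefix)
    vpath = prefix.parent / (prefix.name + "_vertices.tsv")
    ppath = prefix.parent / (prefix.name + "_parcels.tsv")
    vdf = _read_tsv_numeric(vpath, ["vertex_id", "parcel_id"])
    pdf = pd.read_csv(ppath, sep="\t")
    if n_vertices is not None and len(vdf) != n_vertices:
        raise ValueError(
            f"{vpath}: labels cover {len(vdf)} vertices but the surface has {n_vertices}"
        )
    vdf = vdf.sort_values("vertex_id")
    order = np.argsort(pdf["parcel_id"].to_numpy())
    pdf = pdf.iloc[order]
    names_by_net: dict[int, str] = {}
    for net, name in zip(pdf["network_id"], pdf["network_name"]):
        names_by_net[int(net)] = str(name)
    network_names = [names_by_net[k] for k in sorted(names_by_net)]
    return ParcelLabeling(
        vdf["parcel_id"].to_numpy(), pdf["network_id"].to_numpy(), network_names
    )


# ---------------------------------------------------------------------------
# time series (TSV + JSON sidecar)


def _read_tsv_numeric(path: Path, expected_cols: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if expected_cols is not None:
        missing = set(expected_cols) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value at row {row + 2}, column {col!r}")
        df[col] = coerced
    return df


def write_timeseries(ts: ParcelTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    cols = [f"parcel_{p}" for p in range(1, ts.n_parcels + 1)]
    pd.DataFrame(ts.data, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "sampling_interval_s": ts.sampling_interval_s,
                "subject": ts.subject_id,
                "run": ts.run_id,
                "condition": ts.condition,
            },
            fh,
        )
    return path


def read_timeseries(path: str | Path) -> ParcelTimeSeries:
    path = Path(path)
    df = _read_tsv_numeric(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"sampling_interval_s": 1.0, "subject": "sub-01", "run": "run-01",
            "condition": "rest"}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta.update(json.load(fh))
    return ParcelTimeSeries(
        df.to_numpy(dtype=float),
        sampling_interval_s=float(meta["sampling_interval_s"]),
        subject_id=str(meta["subject"]),
        run_id=str(meta["run"]),
        condition=str(meta["condition"]),
    )


# ---------------------------------------------------------------------------
# matrices


def write_matrix(matrix: np.ndarray, path: str | Path, labels: list[str] | None = None,
                 sidecar: dict | None = None) -> Path:
    path = Path(path)
    m = np.asarray(matrix, dtype=float)
    if labels is None:
        labels = [f"parcel_{i}" for i in range(1, m.shape[1] + 1)]
    pd.DataFrame(m, columns=labels).to_csv(path, sep="\t", index=False,
                                           float_format="%.17g")
    if sidecar:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, default=str)
    return path


def read_matrix(path: str | Path) -> np.ndarray:
    return _read_tsv_numeric(Path(path)).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# events (BIDS-style)


def write_events(design: TaskDesign, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "onset": design.onsets,
            "duration": design.durations,
            "trial_type": design.trial_types,
            "modulator": design.modulators,
            "correct": design.correct.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_events(path: str | Path) -> TaskDesign:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    required = {"onset", "duration", "trial_type", "modulator", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return TaskDesign(
        df["onset"].to_numpy(dtype=float),
        df["duration"].to_numpy(dtype=float),
        df["trial_type"].to_numpy(),
        df["modulator"].to_numpy(dtype=float),
        df["correct"].to_numpy(dtype=bool),
    )


# ---------------------------------------------------------------------------
# manifests


def write_manifest(out_dir: str | Path, config: dict, seed: int, stage: str) -> Path:
    """Reproducibility manifest: config hash, seed and stage version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
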