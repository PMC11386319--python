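"""File formats: NIfTI volumes/masks, TSV tables, cohort persistence,
and parameter sidecars.

Conventions: tables are tab-separated UTF-8 with a header row; volumes
are NIfTI-1; voxel indices are 0-based and in-mask voxels are ordered
x-fastest (see :mod:`ccgrad.masks`).  Every numeric table gets a JSON
sidecar recording the parameters and seeds that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .masks import MaskGeometry
from .synthetic import CELLS, CohortConfig, CohortTable, PlantedTruth, SubjectRecord

REQUIRED_COLUMNS = ("id", "diagnosis", "age", "sex", "site")
SCORE_COLUMNS = ("inattention", "hyperactivity_impulsivity")


def derive_age_group(age: float) -> str:
    if 7.0 <= age < 12.0:
        return "child"
    if 12.0 <= age <= 18.0:
        return "adolescent"
    raise ValueError(f"age {age} outside the 7.0-18.0 study range")


def read_subjects_table(path) -> pd.DataFrame:
    """Read and validate a subjects TSV; derives ``age_group``.

    Required columns: id, diagnosis, age, sex, site; symptom columns are
    optional (missing entries are kept as NaN and excluded from the
    clinical stage only).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "site": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")
    groups = []
    for i, row in df.iterrows():
        if row["diagnosis"] not in ("ADHD", "HC"):
            raise ValueError(f"row {i} (id={row['id']}): diagnosis {row['diagnosis']!r}")
        try:
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i} (id={row['id']}): unparseable age") from exc
        try:
            groups.append(derive_age_group(age))
        except ValueError as exc:
            raise ValueError(f"row {i} (id={row['id']}): {exc}") from exc
    df = df.copy()
    df["age"] = df["age"].astype(float)
    df["age_group"] = groups
    for col in SCORE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_subjects_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def save_mask(geom: MaskGeometry, path) -> None:
    nib.save(nib.Nifti1Image(geom.mask.astype(np.int16), geom.affine), str(path))


def load_mask(path, mask_id: str = "mask") -> MaskGeometry:
    img = nib.load(str(path))
    return MaskGeometry(
        mask=np.asanyarray(img.dataobj) > 0, affine=img.affine, mask_id=mask_id
    )


def read_masked_volume(data_path, mask_path, tol: float = 1e-4):
    """Load a 3-D or 4-D NIfTI restricted to a mask.

    Returns ``(values, geometry)`` where values is (V,) for 3-D input or
    (T, V) for 4-D input, in canonical voxel order.  Data and mask must
    share grid and affine within ``tol``.
    """
    img = nib.load(str(data_path))
    geom = load_mask(mask_path)
    data = np.asanyarray(img.dataobj)
    if data.shape[:3] != geom.shape or not np.allclose(
        img.affine, geom.affine, atol=tol
    ):
        raise ValueError(
            "data/mask grid mismatch: "
            f"data shape {data.shape[:3]} affine\n{img.affine}\n"
            f"mask shape {geom.shape} affine\n{geom.affine}"
        )
    return geom.vector_from_volume(data), geom


def write_masked_volume(values: np.ndarray, geom: MaskGeometry, path,
                        background: float = np.nan) -> None:
    """Write a per-voxel vector (V,) or stack (n, V) as 3-D/4-D NIfTI."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        vol = geom.volume_from_vector(values, background=background)
    else:
        vol = np.stack(
            [geom.volume_from_vector(v, background=background) for v in values],
            axis=-1,
        )
    nib.save(nib.Nifti1Image(vol.astype(np.float64), geom.affine), str(path))


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_sidecar(path, params: dict) -> None:
    """JSON sidecar (<name>.json) with the parameters behind an artifact."""
    side = Path(path).with_suffix(Path(path).suffix + ".json")
    side.write_text(json.dumps(params, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _truth_to_json(truth: PlantedTruth) -> dict:
    return {
        "cell": truth.cell,
        "u": truth.u.tolist(),
        "v": truth.v.tolist(),
        "network_label": truth.network_label.tolist(),
        "network_label_cb": truth.network_label_cb.tolist(),
        "shifted_sets": {k: np.asarray(v).tolist() for k, v in truth.shifted_sets.items()},
        "symptom_region": truth.symptom_region.tolist(),
    }


def _truth_from_json(d: dict) -> PlantedTruth:
    return PlantedTruth(
        cell=d["cell"],
        u=np.array(d["u"]),
        v=np.array(d["v"]),
        network_label=np.array(d["network_label"], dtype=int),
        network_label_cb=np.array(d["network_label_cb"], dtype=int),
        shifted_sets={k: np.array(v, dtype=int) for k, v in d["shifted_sets"].items()},
        symptom_region=np.array(d["symptom_region"], dtype=int),
    )


def save_cohort(cohort: CohortTable, out_dir) -> None:
    """Write a synthetic cohort to disk (subjects TSV, masks, labels,
    truth sidecar, per-subject data)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_subjects_table(cohort.to_dataframe(), out / "subjects.tsv")
    save_mask(cohort.mask_ctx, out / "cortex_mask.nii.gz")
    save_mask(cohort.mask_cb, out / "cerebellum_mask.nii.gz")
    any_truth = cohort.truth[CELLS[0]]
    write_masked_volume(
        any_truth.network_label.astype(float), cohort.mask_ctx,
        out / "parcellation_cortex.nii.gz", background=0.0,
    )
    write_masked_volume(
        any_truth.network_label_cb.astype(float), cohort.mask_cb,
        out / "parcellation_cerebellum.nii.gz", background=0.0,
    )
    (out / "truth.json").write_text(
        json.dumps({c: _truth_to_json(t) for c, t in cohort.truth.items()}, indent=2)
        + "\n"
    )
    (out / "config.json").write_text(
        json.dumps(asdict(cohort.config), indent=2, default=_jsonify) + "\n"
    )
    sub_dir = out / "subjects"
    sub_dir.mkdir(exist_ok=True)
    for rec in cohort.records:
        handle = cohort.data[rec.id]
        if cohort.config.mode == "timeseries":
            ts_ctx, ts_cb = handle
            write_masked_volume(
                ts_ctx, cohort.mask_ctx, sub_dir / f"{rec.id}_cortex.nii.gz",
                background=0.0,
            )
            write_masked_volume(
                ts_cb, cohort.mask_cb, sub_dir / f"{rec.id}_cerebellum.nii.gz",
                background=0.0,
            )
        else:
            path = sub_dir / f"{rec.id}_connectivity.npy"
            np.save(path, handle)
            write_sidecar(
                path,
                {"shape": list(handle.shape), "scale": "r",
                 "source_mask": "cortex", "target_mask": "cerebellum"},
            )


def load_cohort(in_dir) -> CohortTable:
    """Inverse of :func:`save_cohort`."""
    src = Path(in_dir)
    config = CohortConfig(**json.loads((src / "config.json").read_text()))
    df = read_subjects_table(src / "subjects.tsv")
    mask_ctx = load_mask(src / "cortex_mask.nii.gz", "cortex")
    mask_cb = load_mask(src / "cerebellum_mask.nii.gz", "cerebellum")
    truth = {
        c: _truth_from_json(d)
        for c, d in json.loads((src / "truth.json").read_text()).items()
    }
    records = []
    data = {}
    for _, row in df.iterrows():
        rec = SubjectRecord(
            id=row["id"], diagnosis=row["diagnosis"], age_years=row["age"],
            age_group=row["age_group"], sex=row["sex"], site=row["site"],
            inattention=row.get("inattention", np.nan),
            hyperactivity_impulsivity=row.get("hyperactivity_impulsivity", np.nan),
        )
        records.append(rec)
        sub = src / "subjects"
        if config.mode == "timeseries":
            ts_ctx, _ = read_masked_volume(
                sub / f"{rec.id}_cortex.nii.gz", src / "cortex_mask.nii.gz"
            )
            ts_cb, _ = read_masked_volume(
                sub / f"{rec.id}_cerebellum.nii.gz", src / "cerebellum_mask.nii.gz"
            )
            data[rec.id] = (ts_ctx, ts_cb)
        else:
            data[rec.id] = np.load(sub / f"{rec.id}_connectivity.npy")
    return CohortTable(
        records=records, data=data, truth=truth,
        mask_ctx=mask_ctx, mask_cb=mask_cb, config=config,
    )
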