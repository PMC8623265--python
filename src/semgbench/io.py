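"""Plain-text I/O: signal files, study manifests, feature tables, models.

Signals are delimited text (one column per channel, header CH1..CH4);
the manifest is a tab-separated table with one row per recording
(subject, gesture, day, fatigue, angle, group, sampling_rate, path).
Everything round-trips losslessly enough for the analysis (signals at
"%.6g").
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .core import ConditionKey, DatasetRegistry, Recording
from .classifiers import LDAModel, PNNModel

MANIFEST_COLUMNS = [
    "subject",
    "gesture",
    "day",
    "fatigue",
    "angle",
    "group",
    "sampling_rate",
    "path",
]
MANIFEST_NAME = "manifest.tsv"


def write_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(recording.samples.T, columns=list(recording.channel_names))
    df.to_csv(path, index=False, float_format="%.6g")


def read_recording(
    path: str | Path,
    sampling_rate: float,
    gesture_id: str,
    subject_id: str,
    condition: ConditionKey,
    group: int,
) -> Recording:
    df = pd.read_csv(path)
    return Recording(
        samples=df.to_numpy(dtype=float).T,
        sampling_rate=sampling_rate,
        gesture_id=gesture_id,
        subject_id=subject_id,
        condition=condition,
        group=group,
        channel_names=tuple(df.columns),
    )


def write_study(registry: DatasetRegistry, out_dir: str | Path) -> Path:
    """Write every recording plus the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for rec in registry.recordings():
        rel = (
            f"{rec.subject_id}/{rec.condition.label}/"
            f"g{rec.group}_{rec.gesture_id}.csv"
        )
        write_recording(rec, out_dir / rel)
        rows.append(
            {
                "subject": rec.subject_id,
                "gesture": rec.gesture_id,
                "day": rec.condition.day,
                "fatigue": rec.condition.fatigue,
                "angle": rec.condition.angle,
                "group": rec.group,
                "sampling_rate": rec.sampling_rate,
                "path": rel,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / MANIFEST_NAME
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    return df


def build_registry(manifest, base_dir: str | Path | None = None) -> DatasetRegistry:
    """Load recordings listed in a manifest (path or DataFrame) into a registry."""
    if isinstance(manifest, (str, Path)):
        base_dir = Path(manifest).parent if base_dir is None else Path(base_dir)
        manifest = read_manifest(manifest)
    elif base_dir is None:
        base_dir = Path(".")
    base_dir = Path(base_dir)
    registry = DatasetRegistry()
    for row in manifest.itertuples():
        registry.add(
            read_recording(
                base_dir / row.path,
                sampling_rate=float(row.sampling_rate),
                gesture_id=str(row.gesture),
                subject_id=str(row.subject),
                condition=ConditionKey(str(row.day), str(row.fatigue), int(row.angle)),
                group=int(row.group),
            )
        )
    return registry


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- model persistence: named delimited blocks in one text file ---------------

def _write_block(fh, name: str, array: np.ndarray) -> None:
    array = np.atleast_2d(np.asarray(array, dtype=float))
    fh.write(f"@{name} {array.shape[0]} {array.shape[1]}\n")
    np.savetxt(fh, array, fmt="%.17g")


def save_model(model, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if isinstance(model, LDAModel):
            fh.write("#model lda\n")
            fh.write("#classes " + " ".join(model.classes) + "\n")
            fh.write("#columns " + " ".join(model.feature_columns) + "\n")
            fh.write(f"#regularization {float(model.regularization)!r}\n")
            _write_block(fh, "W", model.W)
            _write_block(fh, "class_means_projected", model.class_means_projected)
            _write_block(fh, "Sw", model.Sw)
            _write_block(fh, "Sb", model.Sb)
            _write_block(fh, "eigenvalues", model.eigenvalues)
        elif isinstance(model, PNNModel):
            fh.write("#model pnn\n")
            fh.write("#classes " + " ".join(model.classes) + "\n")
            fh.write("#columns " + " ".join(model.feature_columns) + "\n")
            fh.write(f"#sigma {float(model.sigma)!r}\n")
            _write_block(fh, "exemplars", model.exemplars)
            _write_block(fh, "T", model.T)
        else:
            raise TypeError(f"unsupported model {type(model).__name__}")


def load_model(path: str | Path):
    meta: Dict[str, str] = {}
    blocks: Dict[str, np.ndarray] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("#"):
            key, _, value = line[1:].partition(" ")
            meta[key] = value
            i += 1
        elif line.startswith("@"):
            name, r, c = line[1:].split()
            r, c = int(r), int(c)
            data = np.array(
                [[float(v) for v in lines[i + 1 + j].split()] for j in range(r)]
            ).reshape(r, c)
            blocks[name] = data
            i += 1 + r
        else:
            i += 1
    classes = meta["classes"].split()
    columns = meta["columns"].split()
    if meta["model"] == "lda":
        return LDAModel(
            W=blocks["W"],
            class_means_projected=blocks["class_means_projected"],
            classes=classes,
            Sw=blocks["Sw"],
            Sb=blocks["Sb"],
            regularization=float(meta["regularization"]),
            eigenvalues=blocks["eigenvalues"].ravel(),
            feature_columns=columns,
        )
    if meta["model"] == "pnn":
        sigma = float(meta["sigma"])
        return PNNModel(
            exemplars=blocks["exemplars"],
            b=0.8326 / sigma,
            T=blocks["T"],
            classes=classes,
            sigma=sigma,
            feature_columns=columns,
        )
    raise ValueError(f"unknown model kind {meta.get('model')!r} in {path}")
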