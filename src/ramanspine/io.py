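"""Plain-text persistence for spectra, metadata, configs and models.

Spectra travel as a wide delimited table whose first row is the wavenumber
axis and each subsequent row one spectrum, with a sidecar metadata table
(label, animal, vertebra, site or depth, integration time).  Trained
models serialize to a single JSON document carrying the axis hash, task,
selected wavenumbers, weights and calibration so predictions are
reproducible without retraining.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import FeatureSet, TaskSpec, TrainedModel, TASKS
from .preprocess import Fingerprint
from .synth import RawAcquisition, SpectraDataset, SpectralAxis


def axis_hash(axis: SpectralAxis) -> str:
    return hashlib.sha256(axis.wavenumbers.tobytes()).hexdigest()[:16]


def write_spectra(path, axis: SpectralAxis, matrix: np.ndarray) -> None:
    """Wide table: first row wavenumbers, one spectrum per following row."""
    out = np.vstack([axis.wavenumbers, np.atleast_2d(matrix)])
    pd.DataFrame(out).to_csv(path, index=False, header=False)


def read_spectra(path) -> tuple[SpectralAxis, np.ndarray]:
    raw = pd.read_csv(path, header=None).to_numpy(dtype=float)
    wn = raw[0]
    resolution = float(np.mean(np.diff(wn)))
    return SpectralAxis(wavenumbers=wn, resolution=resolution), raw[1:]


def write_dataset(prefix, dataset: SpectraDataset) -> tuple[Path, Path]:
    """Dataset as spectra table (accumulation-averaged raw counts) + metadata."""
    prefix = Path(prefix)
    matrix = np.vstack([a.counts.mean(axis=0) for a in dataset.acquisitions])
    spectra_path = prefix.with_suffix(".spectra.csv")
    meta_path = prefix.with_suffix(".meta.csv")
    write_spectra(spectra_path, dataset.axis, matrix)
    meta = pd.DataFrame([
        {"label": a.tissue_label,
         "integration_time": a.integration_time,
         **a.site_metadata}
        for a in dataset.acquisitions])
    meta.to_csv(meta_path, index=False)
    return spectra_path, meta_path


def write_fingerprints(prefix, fps: list[Fingerprint]) -> tuple[Path, Path]:
    prefix = Path(prefix)
    matrix = np.vstack([fp.intensities for fp in fps])
    spectra_path = prefix.with_suffix(".fingerprints.csv")
    write_spectra(spectra_path, fps[0].axis, matrix)
    prov_path = prefix.with_suffix(".provenance.json")
    prov_path.write_text(json.dumps(
        {"steps": [list(s) for s in fps[0].provenance],
         "labels": [fp.tissue_label for fp in fps]}, indent=1))
    return spectra_path, prov_path


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if "seed" not in cfg:
        raise ValueError("config file must set a seed")
    return cfg


def save_model(path, model: TrainedModel) -> None:
    doc = {
        "task": model.task.name,
        "classes": list(model.classes),
        "C1": model.C1,
        "C2": model.C2,
        "bin_indices": model.features.bin_indices.tolist(),
        "wavenumbers": model.features.wavenumbers.tolist(),
        "selection_weights": model.features.weights.tolist(),
        "coef": model.coef.tolist(),
        "intercept": model.intercept.tolist(),
        "calibration": [list(c) for c in model.calibration],
        "axis_wavenumbers": (model.axis_wavenumbers.tolist()
                             if model.axis_wavenumbers is not None else None),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    task = TASKS[doc["task"]]
    features = FeatureSet(
        bin_indices=np.array(doc["bin_indices"], dtype=int),
        wavenumbers=np.array(doc["wavenumbers"], dtype=float),
        weights=np.array(doc["selection_weights"], dtype=float))
    return TrainedModel(
        task=task, features=features, classes=tuple(doc["classes"]),
        coef=np.array(doc["coef"], dtype=float),
        intercept=np.array(doc["intercept"], dtype=float),
        calibration=[tuple(c) for c in doc["calibration"]],
        C1=doc["C1"], C2=doc["C2"],
        axis_wavenumbers=(np.array(doc["axis_wavenumbers"], dtype=float)
                          if doc["axis_wavenumbers"] is not None else None))
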