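"""Spectrum/cohort data model and file I/O.

Native formats are deliberately plain text: per-spectrum two-column CSV
(``mz,intensity``), a cohort manifest CSV (``sample_id,label,chip_id,path``),
a JSON tree-model schema, and a YAML pipeline configuration. A minimal
read-only mzML parser is provided for interoperability.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

NODE_POSITIVE = "node_positive"
NODE_NEGATIVE = "node_negative"
UNLABELLED = "unlabelled"
ALLOWED_LABELS = (NODE_POSITIVE, NODE_NEGATIVE, UNLABELLED)

TREE_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """A file failed to parse as one of the pipeline's formats."""


@dataclass
class Spectrum:
    """One mass spectrum: an m/z axis (Da) with intensities plus metadata.

    Invariants: ``mz`` strictly increasing, same length as ``intensity``,
    intensities finite (and nonnegative after preprocessing).
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    label: str = UNLABELLED
    chip_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError(
                f"mz and intensity must be 1-D and equal length "
                f"(got {self.mz.shape} vs {self.intensity.shape})"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.label not in ALLOWED_LABELS:
            raise ValueError(f"unknown label {self.label!r}; allowed: {ALLOWED_LABELS}")

    def __len__(self) -> int:
        return len(self.mz)

    def copy(self) -> "Spectrum":
        return Spectrum(
            sample_id=self.sample_id,
            mz=self.mz.copy(),
            intensity=self.intensity.copy(),
            label=self.label,
            chip_id=self.chip_id,
            meta=dict(self.meta),
        )


@dataclass
class Cohort:
    """A list of spectra with a role (training / test / qc_replicates)."""

    spectra: list = field(default_factory=list)
    role: str = "training"

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.spectra]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def labels(self) -> list:
        return [s.label for s in self.spectra]


@dataclass
class PipelineConfig:
    """Analysis settings for preprocessing, detection and screening."""

    mz_min: float = 2000.0
    mz_max: float = 20000.0
    snr_first_pass: float = 3.0
    min_peak_threshold: float = 0.20
    cluster_window: float = 0.005
    snr_second_pass: float = 2.0
    baseline_half_width: float = 150.0
    noise_window_points: int = 151
    cv_folds: int = 10
    alpha_report: float = 0.05
    alpha_strict: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mz_min < self.mz_max):
            raise ValueError("require 0 < mz_min < mz_max")
        if self.snr_second_pass > self.snr_first_pass:
            raise ValueError("snr_second_pass must be <= snr_first_pass")
        if not (0 < self.min_peak_threshold <= 1):
            raise ValueError("min_peak_threshold must be in (0, 1]")


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file (``pipeline:`` section or flat)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    section = data.get("pipeline", data)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(section) - known
    if unknown:
        raise FormatError(f"unknown pipeline config keys: {sorted(unknown)}")
    return PipelineConfig(**section)


# ---------------------------------------------------------------------------
# Spectrum CSV (and mzML) reading / writing
# ---------------------------------------------------------------------------

def read_spectrum(path, format: str = "csv", **metadata) -> Spectrum:
    """Read one spectrum from a two-column CSV/TSV file or a mzML run.

    CSV files may be comma- or tab-delimited and may carry a header row.
    Rows are sorted by m/z; exact duplicate m/z values are a format error.
    """
    path = Path(path)
    if format == "mzml":
        from seldi_nodal._mzml import read_mzml_spectrum

        mz, inten = read_mzml_spectrum(path)
    elif format == "csv":
        mz, inten = _read_xy_csv(path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")

    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    dup = np.flatnonzero(np.diff(mz) == 0)
    if dup.size:
        raise FormatError(
            f"{path}: duplicate m/z value {mz[dup[0]]:g} (rows would not be "
            f"strictly increasing after sorting)"
        )
    sample_id = metadata.pop("sample_id", path.stem)
    return Spectrum(sample_id=sample_id, mz=mz, intensity=inten, **metadata)


def _read_xy_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            if not (math.isfinite(x) and math.isfinite(y)):
                raise FormatError(f"{path}:{lineno}: non-finite value in {line!r}")
            mzs.append(x)
            intens.append(y)
    if not mzs:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(mzs), np.asarray(intens)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as comma-delimited ``mz,intensity`` with header."""
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for x, y in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{x:.10g},{y:.10g}\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def read_manifest(path, load_spectra: bool = True, role: str = "training") -> Cohort:
    """Read a cohort manifest CSV (``sample_id,label,chip_id,path``).

    Spectrum paths are resolved relative to the manifest's directory. With
    ``load_spectra=False`` the returned cohort holds zero-length spectra
    carrying only metadata (a cohort "skeleton").
    """
    path = Path(path)
    rows = _read_manifest_rows(path)
    spectra = []
    for sample_id, label, chip_id, spec_path in rows:
        full = path.parent / spec_path
        if load_spectra:
            if not full.exists():
                raise FormatError(f"{path}: spectrum file not found: {full}")
            s = read_spectrum(full, sample_id=sample_id, label=label, chip_id=chip_id)
        else:
            s = Spectrum(sample_id, np.array([]), np.array([]), label, chip_id,
                         meta={"path": str(spec_path)})
        spectra.append(s)
    return Cohort(spectra=spectra, role=role)


def _read_manifest_rows(path: Path):
    rows = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        expected = ["sample_id", "label", "chip_id", "path"]
        if cols != expected:
            raise FormatError(f"{path}: manifest header must be {','.join(expected)}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            sample_id, label, chip_id, spec_path = parts
            if label not in ALLOWED_LABELS:
                raise FormatError(
                    f"{path}:{lineno}: unknown label {label!r}; allowed: {ALLOWED_LABELS}"
                )
            if sample_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            rows.append((sample_id, label, chip_id, spec_path))
    return rows


def write_manifest(cohort: Cohort, path, spectrum_paths: Sequence[str]) -> None:
    """Write a manifest CSV for ``cohort``; paths given relative to it."""
    if len(spectrum_paths) != len(cohort):
        raise ValueError("one path per spectrum required")
    with open(path, "w") as fh:
        fh.write("sample_id,label,chip_id,path\n")
        for s, p in zip(cohort, spectrum_paths):
            fh.write(f"{s.sample_id},{s.label},{s.chip_id},{p}\n")


# ---------------------------------------------------------------------------
# Tree model JSON round trip
# ---------------------------------------------------------------------------

def write_tree_model(model, path) -> None:
    """Serialize a TreeModel to JSON (schema v1, '<= threshold goes left')."""
    from seldi_nodal.oblique_tree import LeafNode, SplitNode

    nodes = []
    for node in model.nodes.values():
        if isinstance(node, SplitNode):
            nodes.append({
                "node_id": node.node_id,
                "kind": "split",
                "coefficients": {str(k): float(v) for k, v in node.coefficients.items()},
                "threshold": float(node.threshold),
                "left_child": node.left_child,
                "right_child": node.right_child,
            })
        elif isinstance(node, LeafNode):
            nodes.append({
                "node_id": node.node_id,
                "kind": "leaf",
                "label": node.label,
                "training_counts": dict(node.training_counts),
            })
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown node type {type(node)!r}")
    payload = {
        "schema_version": TREE_SCHEMA_VERSION,
        "convention": "linear combination <= threshold routes left",
        "root_id": model.root_id,
        "nodes": nodes,
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_tree_model(path):
    """Read a TreeModel from JSON written by :func:`write_tree_model`."""
    from seldi_nodal.oblique_tree import LeafNode, SplitNode, TreeModel

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid tree-model JSON: {exc}") from exc
    version = payload.get("schema_version")
    if version != TREE_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: tree-model schema version {version!r} not supported "
            f"(expected {TREE_SCHEMA_VERSION})"
        )
    nodes = {}
    for entry in payload["nodes"]:
        if entry["kind"] == "split":
            node = SplitNode(
                node_id=int(entry["node_id"]),
                coefficients={str(k): float(v) for k, v in entry["coefficients"].items()},
                threshold=float(entry["threshold"]),
                left_child=int(entry["left_child"]),
                right_child=int(entry["right_child"]),
            )
        elif entry["kind"] == "leaf":
            node = LeafNode(
                node_id=int(entry["node_id"]),
                label=str(entry["label"]),
                training_counts={str(k): int(v) for k, v in entry["training_counts"].items()},
            )
        else:
            raise FormatError(f"{path}: unknown node kind {entry['kind']!r}")
        nodes[node.node_id] = node
    model = TreeModel(nodes=nodes, root_id=int(payload["root_id"]),
                      training_meta=payload.get("training_meta", {}))
    model.validate()
    return model
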