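"""Streamline, label, affine and mask I/O.

Internal convention: all coordinates are world millimetres in an RAS frame.
TRK data are converted through the file's voxel-to-world header affine
(treating TRK per its header conventions); TCK data are already world mm.
Voxel grids use 0-based indices and half-open voxel boxes; a NIfTI volume's
center-based affine is shifted by half a voxel to the corner convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas_classify import LabelAssignment
from .errors import FormatError, ValidationError
from .evaluation import VoxelMask
from .tract_model import DEFAULT_N_SAMPLES, TractSet, resample_tract


@dataclass
class RunConfig:
    """All pipeline parameters plus I/O conventions for one run."""

    n_samples: int = DEFAULT_N_SAMPLES
    min_length_mm: float = 20.0
    max_length_mm: float = 200.0
    # grouping
    n_length_ranges: int = 100
    hier_threshold: float = 40.0
    merge_threshold: float = 20.0
    outlier_mass_fraction: float = 0.02
    chi2_level: float = 0.02
    rng_seed: int = 0
    # classifier
    tau_d: float = 50_000.0
    tau_m: float = 300.0
    tau_v: int | None = None
    mode: str = "group"
    hemisphere: str = "both"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if not (0 < self.min_length_mm < self.max_length_mm):
            raise ValidationError("need 0 < min_length_mm < max_length_mm")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise FormatError(f"bad YAML config: {exc}") from exc
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def read_streamlines(path: str | Path, config: RunConfig | None = None) -> TractSet:
    """Load a TRK/TCK file into a resampled, length-filtered TractSet.

    Streamlines outside [min_length_mm, max_length_mm] (raw polyline arc
    length) are dropped; survivors are resampled to ``n_samples``.
    """
    if config is None:
        config = RunConfig()
    path = Path(path)
    try:
        tractogram_file = nib.streamlines.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read streamline file {path}: {exc}") from exc

    tracts = []
    dropped = 0
    for sl in tractogram_file.tractogram.streamlines:   # already RAS mm
        pts = np.asarray(sl, dtype=float)
        if len(pts) < 2:
            dropped += 1
            continue
        length = _polyline_length(pts)
        if not (config.min_length_mm <= length <= config.max_length_mm):
            dropped += 1
            continue
        tracts.append(resample_tract(pts, config.n_samples))
    if not tracts:
        raise ValidationError(
            f"no streamlines survive the [{config.min_length_mm}, "
            f"{config.max_length_mm}] mm window in {path} ({dropped} dropped)"
        )
    return TractSet(tracts=tracts, space_tag="subject")


def write_streamlines(
    tract_set: TractSet, path: str | Path, fmt: str | None = None
) -> None:
    """Write raw polylines as TRK or TCK (inferred from the extension)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("trk", "tck"):
        raise ValidationError(f"unsupported streamline format {fmt!r}")
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(t.raw_points, dtype=np.float32) for t in tract_set.tracts],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))


def read_labels(path: str | Path) -> dict[int, str]:
    """Read a TSV label sidecar (columns: tract_index, label)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"label": str})
    except Exception as exc:
        raise FormatError(f"cannot parse label TSV {path}: {exc}") from exc
    for col in ("tract_index", "label"):
        if col not in df.columns:
            raise FormatError(f"label TSV {path} is missing column {col!r}")
    idx = df["tract_index"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise FormatError(f"label TSV {path} has duplicate tract_index values")
    return {int(i): str(l) for i, l in zip(idx, df["label"])}


def write_labels(
    assignments: list[LabelAssignment] | dict[int, str], path: str | Path
) -> None:
    """Write per-tract labels as TSV; OUTLIER is written literally."""
    if isinstance(assignments, dict):
        rows = sorted(assignments.items())
    else:
        rows = [(a.unit_id, a.label) for a in assignments]
    df = pd.DataFrame(rows, columns=["tract_index", "label"])
    df.to_csv(path, sep="\t", index=False)


def read_affine(path: str | Path) -> np.ndarray:
    """Read a 4x4 affine from a text file (16 numbers, row-major)."""
    try:
        values = np.loadtxt(path, dtype=float)
    except Exception as exc:
        raise FormatError(f"cannot parse affine file {path}: {exc}") from exc
    flat = values.reshape(-1)
    if flat.size != 16:
        raise FormatError(f"affine file {path} must hold 16 numbers, got {flat.size}")
    return flat.reshape(4, 4)


def write_affine(affine: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(affine, dtype=float).reshape(4, 4), fmt="%.17g")


def read_fa_mask(path: str | Path, threshold: float = 0.2) -> VoxelMask:
    """Binary inclusion mask (FA >= threshold) from an axis-aligned NIfTI.

    The NIfTI affine maps voxel centers; the returned mask uses the voxel-
    corner, half-open-box convention, so the origin is shifted by half a
    voxel.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    affine = img.affine
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin))):
        raise FormatError("only axis-aligned NIfTI affines are supported")
    voxel_size = np.abs(np.diag(lin))
    if np.any(np.diag(lin) < 0):
        raise FormatError("negative NIfTI axis directions are not supported")
    data = np.asarray(img.dataobj, dtype=float)
    origin = affine[:3, 3] - voxel_size / 2.0
    return VoxelMask(
        shape=tuple(int(s) for s in data.shape),
        voxel_size=tuple(float(v) for v in voxel_size),
        origin=tuple(float(o) for o in origin),
        occupancy=data >= threshold,
    )


def write_run_manifest(path: str | Path, config: dict, seeds: dict | None = None) -> None:
    """JSON record of versions, configuration and seeds for one run."""
    import tractlabel

    manifest = {
        "tractlabel_version": tractlabel.__version__,
        "numpy_version": np.__version__,
        "nibabel_version": nib.__version__,
        "config": config,
        "seeds": seeds or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
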