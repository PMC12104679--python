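"""Readers, writers and validation for every artifact surface.

CSV dialect: comma-separated, UTF-8, mandatory header row, "." decimal,
NA token ``NA``.  Scene frames are 8-bit RGB PNG; thermal maps are
single-channel float32 TIFF (degC) or plain CSV matrices; masks are 8-bit
0/255 PNG; configs are YAML; the run manifest is JSON.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .colormask import Rect, SceneImage
from .synth import ExperimentConfig

__all__ = [
    "FormatError",
    "TableSchemaError",
    "read_scene",
    "write_scene",
    "read_thermal",
    "write_thermal",
    "read_mask",
    "write_mask",
    "validate_tables",
    "load_config",
    "save_config",
    "RunManifest",
    "ENV_COLUMNS",
    "PHYSIO_COLUMNS",
]

ENV_COLUMNS = ["session", "day", "period", "treatment", "AH", "AT", "SR", "SM", "ST", "EC"]
PHYSIO_COLUMNS = [
    "seedling_id", "treatment", "session", "day", "period", "replicate",
    "SPAD", "Fm_prime", "Fo_prime", "FvFm_prime", "Phi_II", "Phi_NO", "Phi_NPQ",
    "PSI_act", "PSI_open", "qL",
]

NA_TOKEN = "NA"


class FormatError(ValueError):
    """Input file violates the expected image/table format."""


class TableSchemaError(FormatError):
    """Tabular input violates the schema; carries every violation found."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


def read_scene(
    path,
    chart_region: Rect | None = None,
    plant_rois=None,
    session: str = "",
    scene_id: str | None = None,
) -> SceneImage:
    """Load an RGB frame; 16-bit inputs are converted down with a warning."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)  # PIL silently narrows 16-bit TIFFs
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 2:
        raise FormatError(f"{path}: grayscale input, expected 3-channel RGB")
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit image converted to 8-bit")
        arr = (arr / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype}")
    if arr.shape[0] != arr.shape[1]:
        warnings.warn(f"{path}: frame is not 1:1 aspect ({arr.shape[0]}x{arr.shape[1]})")
    return SceneImage(
        image=arr,
        session=session,
        scene_id=scene_id or path.stem,
        chart_region=chart_region,
        plant_rois=list(plant_rois or []),
    )


def write_scene(scene: SceneImage, path) -> None:
    Image.fromarray(scene.image, mode="RGB").save(Path(path))


def read_thermal(path) -> np.ndarray:
    """Load a degC grid from float TIFF or a CSV matrix; NaN marks dead pixels."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise FormatError(f"{path}: thermal TIFF must be single-channel")
        return arr.astype(np.float32)
    rows = []
    width = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(cells)} cells, expected {width}"
                )
            vals = []
            for colno, cell in enumerate(cells, start=1):
                cell = cell.strip()
                if cell in ("", NA_TOKEN, "nan", "NaN"):
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}:{colno}: non-numeric cell {cell!r}"
                    ) from None
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty thermal matrix")
    return np.asarray(rows, dtype=np.float32)


def write_thermal(grid: np.ndarray, path) -> None:
    path = Path(path)
    grid = np.asarray(grid, dtype=np.float32)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, grid)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for row in grid:
                fh.write(",".join(NA_TOKEN if np.isnan(v) else repr(float(v)) for v in row))
                fh.write("\n")


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return arr >= 128


def write_mask(mask: np.ndarray, path) -> None:
    arr = (np.asarray(mask, dtype=bool) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)


def validate_tables(env_csv, physio_csv, required_physio=None):
    """Load and validate the environment and physiology tables.

    Every schema violation is collected and reported together, not just the
    first one.
    """
    violations = []
    env = _read_csv(env_csv)
    physio = _read_csv(physio_csv)

    missing = [c for c in ENV_COLUMNS if c not in env.columns]
    if missing:
        violations.append(f"environment table missing columns: {missing}")
    missing_p = [c for c in PHYSIO_COLUMNS if c not in physio.columns]
    if missing_p:
        violations.append(f"physiology table missing columns: {missing_p}")
    for col in set(required_physio or []):
        if col not in physio.columns:
            violations.append(
                f"physiology table lacks requested covariate {col!r} "
                "(required by the regression stage)"
            )
    if "AH" in env.columns:
        bad = env[(env.AH < 0) | (env.AH > 100)]
        if not bad.empty:
            violations.append(
                f"AH outside [0, 100] percent in {len(bad)} row(s), "
                f"first at index {bad.index[0]}"
            )
    if "SR" in env.columns and (env.SR < 0).any():
        violations.append("negative solar radiation values present")
    if "period" in env.columns:
        bad = set(env.period.unique()) - {"M", "E"}
        if bad:
            violations.append(f"invalid period labels: {sorted(bad)}")
    if violations:
        raise TableSchemaError(violations)
    return env, physio


def load_config(path) -> ExperimentConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    try:
        cfg = ExperimentConfig.from_dict(data)
        cfg.validate()
    except TypeError as exc:
        raise FormatError(f"{path}: unknown configuration keys ({exc})") from exc
    return cfg


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    seed: int
    config: dict
    version: str
    inputs: dict = field(default_factory=dict)  # path -> sha256
    row_counts: dict = field(default_factory=dict)  # stage -> rows

    def add_file(self, path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def verify(self) -> list:
        """Return the paths whose checksum no longer matches."""
        return [p for p, digest in self.inputs.items() if sha256_of(p) != digest]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "seed": self.seed, "config": self.config, "version": self.version,
                "inputs": self.inputs, "row_counts": self.row_counts,
            },
            indent=2, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            seed=data["seed"], config=data["config"], version=data["version"],
            inputs=data.get("inputs", {}), row_counts=data.get("row_counts", {}),
        )
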