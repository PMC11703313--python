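"""Batch orchestration: segmentation NIfTIs in, tortuosity CSV out.

One row is produced per (input file, label).  Individual vessel failures —
an absent label, a looped or fragmented skeleton — become rows carrying the
error code in the ``warnings`` column with NaN metrics, so a bad
segmentation never aborts a clinical batch.  The run is deterministic for a
fixed configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import skeleton as _skeleton
from . import spline as _spline
from .errors import TortuosityError
from .metrics import CSV_COLUMNS, TortuosityRecord
from .volume import LabelVolume

__all__ = [
    "PipelineConfig",
    "analyze_volume",
    "analyze_points",
    "run_pipeline",
    "validate_report",
    "read_config_file",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for a batch run; flags mirror the CLI one-to-one."""

    inputs: list                     # NIfTI files (or one directory, expanded)
    labels: list                     # target label ids, non-empty
    out_csv: str = "metrics.csv"
    smoothing: object = "auto"       # "auto" (GCV) or a fixed penalty value
    n_curvature_samples: int = 512
    keep_largest: bool = False
    seed: int = 0
    log_level: str = "INFO"
    subject_ids: dict = field(default_factory=dict)  # path stem -> id override

    def __post_init__(self):
        if not self.labels:
            raise ValueError("label list must be non-empty")
        self.inputs = [Path(p) for p in self.inputs]

    def resolved_inputs(self) -> list:
        files = []
        for p in self.inputs:
            if p.is_dir():
                files.extend(sorted(p.glob("*.nii")) + sorted(p.glob("*.nii.gz")))
            else:
                if not p.exists():
                    raise FileNotFoundError(f"input not found: {p}")
                files.append(p)
        return files


def analyze_points(
    points,
    smoothing="auto",
    n_curvature_samples: int = 512,
    subject_id: str = "",
    label: int = 1,
    n_endpoints: int = 2,
    warnings=(),
) -> TortuosityRecord:
    """Spline fit + curvature metrics for an already-ordered point list."""
    spl = _spline.fit_unit_speed_spline(points, smoothing=smoothing)
    prof = _spline.curvature_profile(spl, n_samples=n_curvature_samples)
    quality = _spline.fit_rmse(spl, points)
    return _metrics.compute_all(
        spl, prof, points, quality,
        subject_id=subject_id, label=label,
        n_endpoints=n_endpoints, warnings=warnings,
    )


def analyze_volume(
    volume: LabelVolume,
    label: int,
    smoothing="auto",
    n_curvature_samples: int = 512,
    keep_largest: bool = False,
    subject_id: str = "",
) -> TortuosityRecord:
    """Full pipeline for one label of one volume: centerline → spline → metrics."""
    path = _skeleton.extract_centerline(volume, label, keep_largest=keep_largest)
    return analyze_points(
        path,
        smoothing=smoothing,
        n_curvature_samples=n_curvature_samples,
        subject_id=subject_id,
        label=label,
        n_endpoints=path.n_endpoints,
        warnings=path.warnings,
    )


def _error_row(subject_id: str, label: int, code: str) -> dict:
    row = {c: math.nan for c in CSV_COLUMNS}
    row.update(
        subject_id=subject_id, label=label,
        n_skeleton_points=0, n_endpoints=0, warnings=f"error:{code}",
    )
    return row


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run the batch described by ``config`` and write the metrics CSV.

    Returns the emitted table.  Per-vessel failures are logged and written
    as error rows; only unreadable inputs abort the run.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    rows = []
    for path in config.resolved_inputs():
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        subject = config.subject_ids.get(stem, stem)
        try:
            volume = LabelVolume.load(path)
        except Exception as exc:
            raise RuntimeError(f"failed to read NIfTI {path}: {exc}") from exc
        for label in config.labels:
            try:
                rec = analyze_volume(
                    volume, label,
                    smoothing=config.smoothing,
                    n_curvature_samples=config.n_curvature_samples,
                    keep_largest=config.keep_largest,
                    subject_id=subject,
                )
                rows.append(rec.as_row())
            except TortuosityError as exc:
                log.warning("%s label %d failed: %s", subject, label, exc)
                rows.append(_error_row(subject, label, exc.code))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    out = Path(config.out_csv)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False)
    log.info("wrote %d rows to %s", len(df), out)
    return df


def validate_report(
    csv_path,
    rmse_max: float = 1.0,
    combined_max: float | None = None,
) -> pd.DataFrame:
    """Quality summary: vessels whose fit quality exceeds the thresholds.

    Flags rows with spline RMSE above ``rmse_max`` mm, combined quality
    above ``combined_max`` (if given), or an error code.  Raises
    ``ValueError`` on an empty or malformed CSV.
    """
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise ValueError(f"cannot parse metrics CSV {csv_path}: {exc}") from exc
    missing = set(CSV_COLUMNS) - set(df.columns)
    if df.empty or missing:
        raise ValueError(
            f"malformed metrics CSV {csv_path}: empty or missing {sorted(missing)}"
        )
    warn = df["warnings"].fillna("").astype(str)
    flagged = (
        (df["spline_rmse_mm"] > rmse_max)
        | warn.str.contains("error:")
        | df["spline_rmse_mm"].isna()
    )
    if combined_max is not None:
        flagged |= df["combined_quality"] > combined_max
    return df[flagged].copy()


def read_config_file(path) -> dict:
    """Flat key=value config file; '#' starts a comment; CLI flags override."""
    opts = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        opts[key.replace("-", "_")] = val
    return opts


def dump_diagnostics(spl, profile, path, prefix) -> None:
    """Per-vessel diagnostic CSVs: sampled spline, kappa(s), residuals."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    samples = spl(profile.s)
    pd.DataFrame(
        {
            "s_mm": profile.s,
            "x_mm": samples[:, 0],
            "y_mm": samples[:, 1],
            "z_mm": samples[:, 2],
            "kappa_per_mm": profile.kappa,
            "interior": profile.interior,
        }
    ).to_csv(f"{prefix}_spline.csv", index=False)
    pts = np.asarray(
        path.points_mm if hasattr(path, "points_mm") else path, dtype=float
    )
    residuals = _spline._project_points(spl, pts)
    pd.DataFrame(
        {
            "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
            "residual_mm": residuals,
        }
    ).to_csv(f"{prefix}_residuals.csv", index=False)
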