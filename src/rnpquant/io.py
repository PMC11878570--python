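"""Delimited-text I/O and pipeline configuration.

No standard bioinformatics container exists for autocorrelation curves,
photon traces or droplet amplitude tables, so everything is plain
delimited text with mandatory named header columns:

* ACF curves:     lag_s, g [, g_se]
* photon traces:  counts  (single column) or time_s, counts
* droplet tables: well_id, hex_amplitude, fam_amplitude, is_reference
* dose tables:    dose_per_cell, response_pct, condition, replicate
* time courses:   time_h, value_pct, condition, dose_per_cell

Output tables carry the tool version and resolved-config hash in a
comment header so identical (config, seed) runs are byte-identical and
traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlator import PhotonTrace
from .ddpcr import DropletWell
from .dose import TimeCourse
from .fitting import QcThresholds
from .models import AcfCurve, CONSTANTS, DEFAULT_STRUCTURE_FACTOR

__all__ = [
    "PipelineConfig",
    "read_acf",
    "write_acf",
    "read_photon_trace",
    "write_photon_trace",
    "read_droplet_table",
    "write_droplet_table",
    "read_dose_table",
    "read_timecourse",
    "write_timecourse",
    "write_table",
]


@dataclass
class PipelineConfig:
    """Resolved run configuration; serialized next to every output."""

    structure_factor: float = DEFAULT_STRUCTURE_FACTOR
    qc: QcThresholds = field(default_factory=QcThresholds)
    chi2_mode: str = "reduced"
    nuclear_volume_l: float = CONSTANTS.hela_nuclear_volume_l
    dye_registry: dict = field(
        default_factory=lambda: {"alexa_594": 3.88e-6, "alexa_488": 4.14e-6}
    )
    n_segments: int = 10
    multitau_m: int = 16
    max_lag_s: float | None = None
    seed: int = 0
    version: str = __version__

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("qc"), dict):
            d["qc"] = QcThresholds(**d["qc"])
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


def _header_lines(config: PipelineConfig | None) -> str:
    h = f"# rnpquant {__version__}\n"
    if config is not None:
        h += f"# config={config.config_hash}\n"
    return h


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(missing)}; "
            f"found: {', '.join(map(str, df.columns))}"
        )


def _sniff_sep(path: str | Path) -> str:
    """Delimiter from the first non-comment line (tab, comma, else whitespace).

    csv.Sniffer misbehaves on single-column files, so keep this simple.
    """
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                if "\t" in line:
                    return "\t"
                if "," in line:
                    return ","
                return r"\s+"
    return "\t"


def _read_delim(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep=_sniff_sep(path), engine="python", comment="#", **kwargs
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: parse error: {exc}") from exc


def write_table(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None
) -> None:
    """Write a result table as tab-separated text with a comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# --- ACF curves ------------------------------------------------------------


def write_acf(curve: AcfCurve, path: str | Path, config: PipelineConfig | None = None) -> None:
    data = {"lag_s": curve.lags, "g": curve.g}
    if curve.g_se is not None:
        data["g_se"] = curve.g_se
    df = pd.DataFrame(data)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        fh.write(f"# n_traces={curve.n_traces} trace_duration_s={curve.trace_duration}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_acf(path: str | Path, meta: dict | None = None) -> AcfCurve:
    df = _read_delim(path)
    _require_columns(df, ["lag_s", "g"], path)
    g_se = df["g_se"].to_numpy() if "g_se" in df.columns else None
    for col in ["lag_s", "g"] + (["g_se"] if g_se is not None else []):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad) and col != "g":  # g may legitimately be checked by AcfCurve
            raise ValueError(f"{path}: non-numeric value in column {col} at data line {bad[0] + 1}")
    return AcfCurve(
        lags=df["lag_s"].to_numpy(dtype=float),
        g=df["g"].to_numpy(dtype=float),
        g_se=g_se,
        meta=meta or {},
    )


# --- photon traces ---------------------------------------------------------


def write_photon_trace(trace: PhotonTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": np.arange(len(trace)) * trace.bin_time,
            "counts": trace.counts,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# rnpquant {__version__}\n# bin_time_s={trace.bin_time!r}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_photon_trace(path: str | Path, bin_time: float | None = None) -> PhotonTrace:
    """Read a trace from two-column (time_s, counts) or one-column text.

    A one-column file requires ``bin_time``; two-column files infer it
    from the time stamps.
    """
    df = _read_delim(path)
    if "counts" in df.columns and "time_s" in df.columns:
        dt = float(np.median(np.diff(df["time_s"].to_numpy(dtype=float))))
        return PhotonTrace(counts=df["counts"].to_numpy(dtype=np.int64), bin_time=dt)
    if df.shape[1] == 1:
        if bin_time is None:
            raise ValueError(f"{path}: single-column trace requires an explicit bin_time")
        return PhotonTrace(
            counts=df.iloc[:, 0].to_numpy(dtype=np.int64), bin_time=bin_time
        )
    raise ValueError(
        f"{path}: expected columns (time_s, counts) or a single counts column; "
        f"found: {', '.join(map(str, df.columns))}"
    )


# --- droplet tables --------------------------------------------------------


def write_droplet_table(wells: list[DropletWell], path: str | Path) -> None:
    frames = []
    for w in wells:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": w.well_id,
                    "hex_amplitude": w.hex_amplitude,
                    "fam_amplitude": w.fam_amplitude,
                    "is_reference": int(w.is_reference),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# rnpquant {__version__}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_droplet_table(path: str | Path) -> list[DropletWell]:
    df = _read_delim(path)
    _require_columns(
        df, ["well_id", "hex_amplitude", "fam_amplitude", "is_reference"], path
    )
    wells = []
    for well_id, sub in df.groupby("well_id", sort=True):
        wells.append(
            DropletWell(
                hex_amplitude=sub["hex_amplitude"].to_numpy(dtype=float),
                fam_amplitude=sub["fam_amplitude"].to_numpy(dtype=float),
                well_id=str(well_id),
                is_reference=bool(sub["is_reference"].iloc[0]),
            )
        )
    return wells


# --- dose tables and time courses ------------------------------------------


def read_dose_table(path: str | Path) -> pd.DataFrame:
    df = _read_delim(path)
    _require_columns(df, ["dose_per_cell", "response_pct", "condition"], path)
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_h": tc.times,
            "value_pct": tc.values,
            "condition": tc.condition,
            "dose_per_cell": tc.dose_per_cell,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# rnpquant {__version__}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_timecourse(path: str | Path) -> list[TimeCourse]:
    df = _read_delim(path)
    _require_columns(df, ["time_h", "value_pct", "condition"], path)
    out = []
    for cond, sub in df.groupby("condition", sort=True):
        sub = sub.sort_values("time_h")
        out.append(
            TimeCourse(
                times=sub["time_h"].to_numpy(dtype=float),
                values=sub["value_pct"].to_numpy(dtype=float),
                condition=str(cond),
                dose_per_cell=(
                    float(sub["dose_per_cell"].iloc[0])
                    if "dose_per_cell" in sub.columns
                    else float("nan")
                ),
            )
        )
    return out
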