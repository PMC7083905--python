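"""File formats: TIFF movies with YAML metadata sidecars, CSV tables for
foci/events/dwells/CRTDs, and JSON fit results.

Conventions: times in seconds, frames 0-based, pixel coordinates 0-based
with the origin at the top-left pixel centre.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import FOCI_COLUMNS
from .kinetics import CRTD, BootstrapResult, CRTDGlobalResults
from .protocol import AcquisitionProtocol
from .simulate import MovieStack
from .track import EVENT_COLUMNS

__all__ = [
    "write_movie",
    "read_movie",
    "read_csv_checked",
    "write_foci_table",
    "read_foci_table",
    "write_events_table",
    "read_events_table",
    "write_dwell_table",
    "read_dwell_table",
    "write_crtd_table",
    "read_crtd_table",
    "write_fit_json",
    "read_fit_json",
]

DWELL_COLUMNS = ["condition_id", "n_frames", "dwell_s", "censored"]
CRTD_CSV_COLUMNS = ["condition_id", "tau_int_s", "tau_d_s", "t_s", "count"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# ---------------------------------------------------------------------------
# Movies
# ---------------------------------------------------------------------------

def _sidecar_path(movie_path: Path) -> Path:
    return movie_path.with_suffix(".yaml")


def write_movie(path, movie: MovieStack) -> Path:
    """Write a multi-page TIFF plus a YAML sidecar with the acquisition
    protocol, condition index and rendering noise parameters."""
    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.float32), photometric="minisblack")
    meta = {
        "protocol": movie.protocol.to_dict(),
        "condition_index": int(movie.condition_index),
        "noise": movie.noise_dict(),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_movie(path) -> MovieStack:
    """Read a TIFF movie and its mandatory YAML metadata sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"movie {path} has no metadata sidecar {sidecar.name}; supply the "
            "acquisition protocol as YAML with keys 'protocol' "
            "(tau_int, tau_d_list, n_bleach_frames, n_frames, pixel_size_nm, "
            "field_shape), 'condition_index' and optionally 'noise'"
        )
    data = np.asarray(tifffile.imread(path), dtype=np.float32)
    if data.ndim != 3:
        raise SchemaError(f"expected a 3-D movie stack in {path}, got shape {data.shape}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    for key in ("protocol", "condition_index"):
        if key not in meta:
            raise SchemaError(f"metadata sidecar {sidecar} missing key '{key}'")
    protocol = AcquisitionProtocol.from_dict(meta["protocol"])
    noise = meta.get("noise", {})
    return MovieStack(
        data=data,
        protocol=protocol,
        condition_index=int(meta["condition_index"]),
        psf_sigma_px=float(noise.get("psf_sigma_px", np.nan)),
        spot_amplitude=float(noise.get("spot_amplitude", np.nan)),
        background=float(noise.get("background", 0.0)),
        camera_offset=float(noise.get("camera_offset", 0.0)),
        read_noise=float(noise.get("read_noise", 0.0)),
    )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_csv_checked(path, required_columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def write_foci_table(path, foci: pd.DataFrame) -> Path:
    path = Path(path)
    foci.loc[:, FOCI_COLUMNS].to_csv(path, index=False)
    return path


def read_foci_table(path) -> pd.DataFrame:
    return read_csv_checked(path, FOCI_COLUMNS)


def write_events_table(path, events: pd.DataFrame) -> Path:
    path = Path(path)
    cols = [c for c in EVENT_COLUMNS + ["dwell_s", "censored"] if c in events.columns]
    events.loc[:, cols].to_csv(path, index=False)
    return path


def read_events_table(path) -> pd.DataFrame:
    return read_csv_checked(path, EVENT_COLUMNS)


def write_dwell_table(path, dwells: pd.DataFrame) -> Path:
    path = Path(path)
    dwells.loc[:, [c for c in DWELL_COLUMNS if c in dwells.columns]].to_csv(path, index=False)
    return path


def read_dwell_table(path) -> pd.DataFrame:
    return read_csv_checked(path, ["condition_id", "dwell_s"])


def write_crtd_table(path, crtds) -> Path:
    """Write CRTDs as long-format CSV (condition_id, tau_int_s, tau_d_s,
    t_s, count), the layout a journal source-data CRTD export uses."""
    rows = []
    for crtd in crtds:
        for t, c in zip(crtd.times, crtd.counts):
            rows.append(
                {
                    "condition_id": crtd.condition_id,
                    "tau_int_s": crtd.tau_int,
                    "tau_d_s": crtd.tau_d,
                    "t_s": t,
                    "count": c,
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=CRTD_CSV_COLUMNS).to_csv(path, index=False)
    return path


def read_crtd_table(path) -> list[CRTD]:
    """Read a long-format CRTD CSV back into per-condition CRTD objects."""
    df = read_csv_checked(path, CRTD_CSV_COLUMNS)
    crtds = []
    for ci, g in df.groupby("condition_id"):
        g = g.sort_values("t_s")
        tau_int = float(g["tau_int_s"].iloc[0])
        tau_d = float(g["tau_d_s"].iloc[0])
        tau_tl = tau_int + tau_d
        m = np.round(g["t_s"].to_numpy() / tau_tl).astype(int)
        if not np.array_equal(m, np.arange(1, m.size + 1)):
            raise SchemaError(
                f"{path}: condition {ci} time grid is not consecutive "
                f"multiples of tau_tl={tau_tl:g}"
            )
        crtds.append(
            CRTD(condition_id=int(ci), tau_int=tau_int, tau_d=tau_d,
                 counts=g["count"].to_numpy(dtype=float))
        )
    return crtds


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

def write_fit_json(path, results: CRTDGlobalResults,
                   bootstrap: BootstrapResult | None = None,
                   selection=None) -> Path:
    payload = {"fit": results.to_dict()}
    if bootstrap is not None:
        payload["bootstrap"] = bootstrap.to_dict()
    if selection is not None:
        payload["selection"] = {
            "order": selection.order,
            "bic_events": {str(k): v for k, v in selection.bic_events.items()},
            "bic": {str(k): v for k, v in selection.bic.items()},
            "rss": {str(k): v for k, v in selection.rss.items()},
            "delta_bic": selection.delta_bic,
        }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def read_fit_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
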