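"""Synthetic single-molecule interval-imaging data.

Generates ground-truth binding events from an exponential-mixture
dissociation model, converts them to observed frame counts under any
dark-interval condition (photobleaching acts only during illuminated
exposures), and optionally renders diffraction-limited spots on a noisy
camera background so the detection and tracking stages can be scored
against known truth.

Conventions
-----------
* Phase-II frames are indexed 0-based; frame ``m`` occupies real time
  ``[m*tau_tl, (m+1)*tau_tl)`` with the first ``tau_int`` seconds
  illuminated.
* An event is counted in a frame only if it is bound for the whole frame
  period and has not photobleached; partial-frame binding at either end is
  ignored.  For exponential dwells this makes observed frame counts
  geometric with per-frame survival
  ``exp(-k_off*tau_tl) * exp(-k_b*tau_int)``.
* Events with zero observed frames are dropped (never seen by the camera).
* Bound molecules do not move; events still visible in the final frame are
  flagged censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .protocol import AcquisitionProtocol, KineticModel

__all__ = [
    "GROUND_TRUTH_COLUMNS",
    "MovieStack",
    "sample_dwell_times",
    "simulate_observed_frames",
    "simulate_events",
    "simulate_dwell_dataset",
    "render_movie",
    "make_fixture_dataset",
    "score_detections",
]

GROUND_TRUTH_COLUMNS = [
    "molecule_id",
    "condition_index",
    "binding_start_s",
    "true_bound_duration_s",
    "bleach_exposure_budget_s",
    "observed_first_frame",
    "observed_n_frames",
    "x_px",
    "y_px",
    "censored",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_dwell_times(
    model: KineticModel,
    n: int,
    seed=None,
    return_components: bool = False,
):
    """Draw ``n`` true bound durations from the exponential mixture.

    Returns durations in seconds (``inf`` for a zero-rate component); with
    ``return_components=True`` also returns the 0-based component label of
    each draw so that mixture proportions can be audited.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not isinstance(model, KineticModel):
        raise TypeError("model must be a KineticModel")
    rng = _rng(seed)
    labels = rng.choice(model.n_components, size=n, p=model.amplitudes)
    # Unit-mean exponentials scaled by each draw's lifetime keeps a single
    # stream consumption independent of the mixture labels.
    unit = rng.exponential(size=n)
    durations = unit * model.lifetimes[labels]
    if return_components:
        return durations, labels
    return durations


def simulate_observed_frames(
    durations,
    k_b: float,
    protocol: AcquisitionProtocol,
    condition_index: int,
    seed=None,
    binding_starts=None,
    return_details: bool = False,
):
    """Convert true bound durations into observed frame counts.

    A focus persists into the next frame only if the molecule stays bound
    through one more frame period ``tau_tl`` and survives one more
    illuminated exposure ``tau_int`` of photobleaching; the count is also
    truncated at the end of the single-molecule phase (censoring).

    Parameters
    ----------
    durations : array of float
        True bound durations, seconds.
    k_b : float
        Photobleaching rate per second of illuminated exposure.
    binding_starts : array of float, optional
        Binding times relative to phase-II start; default 0 (bound at the
        first frame).  Events whose visible span is empty are dropped.

    Returns
    -------
    observed frame counts (zero-frame events removed); with
    ``return_details=True``, a DataFrame with one row per *input* event
    (including dropped ones, ``observed_n_frames = 0``).
    """
    protocol._check_condition(condition_index)
    durations = np.asarray(durations, dtype=float)
    if np.any(durations < 0):
        raise ValueError("durations must be non-negative")
    if k_b < 0:
        raise ValueError("k_b must be non-negative")
    rng = _rng(seed)
    tau_tl = protocol.tau_tl(condition_index)
    tau_int = protocol.tau_int
    n = durations.size

    if binding_starts is None:
        starts = np.zeros(n)
    else:
        starts = np.asarray(binding_starts, dtype=float)
        if starts.shape != durations.shape or np.any(starts < 0):
            raise ValueError("binding_starts must be non-negative, same shape as durations")

    # First frame fully covered by the binding interval, and number of
    # whole frame periods the molecule remains bound for.  Unbinding times
    # beyond the phase end are capped before the int cast (the movie ends
    # there anyway, and inf durations must not overflow).
    first_frame = np.ceil(starts / tau_tl - 1e-12).astype(int)
    end_time = np.minimum(starts + durations, (protocol.n_frames + 1) * tau_tl)
    last_bound = np.floor(end_time / tau_tl + 1e-12).astype(int) - 1
    n_bound = np.maximum(last_bound - first_frame + 1, 0)

    # Illuminated-exposure budget before photobleaching: exponential with
    # rate k_b, quantised to whole survived exposures.
    if k_b > 0:
        budget = rng.exponential(1.0 / k_b, size=n)
        n_unbleached = np.floor(budget / tau_int).astype(int)
    else:
        budget = np.full(n, np.inf)
        n_unbleached = np.full(n, np.iinfo(np.int64).max)

    frames_left = np.maximum(protocol.n_frames - first_frame, 0)
    observed = np.minimum(np.minimum(n_bound, n_unbleached), frames_left)
    censored = (observed == frames_left) & (observed > 0)

    if return_details:
        return pd.DataFrame(
            {
                "binding_start_s": starts,
                "true_bound_duration_s": durations,
                "bleach_exposure_budget_s": budget,
                "observed_first_frame": first_frame,
                "observed_n_frames": observed,
                "censored": censored,
            }
        )
    return observed[observed > 0]


def simulate_events(
    model: KineticModel,
    protocol: AcquisitionProtocol,
    condition_index: int,
    n_molecules: int,
    seed=None,
    start_mode: str = "uniform",
    margin_px: float = 5.0,
) -> pd.DataFrame:
    """Ground-truth event table for one condition.

    Draws dwell times, binding-start times (uniform over phase II, or all
    zero with ``start_mode="frame0"``), static positions within the field,
    and the photobleaching-limited observed frame span.  Events that never
    produce a visible focus are removed; the returned table is the scoring
    reference for detection and tracking.
    """
    if start_mode not in {"uniform", "frame0"}:
        raise ValueError(f"unknown start_mode {start_mode!r}")
    rng = _rng(seed)
    durations = sample_dwell_times(model, n_molecules, seed=rng)
    if start_mode == "uniform":
        starts = rng.uniform(0.0, protocol.phase2_duration(condition_index), size=n_molecules)
    else:
        starts = np.zeros(n_molecules)
    details = simulate_observed_frames(
        durations, model.k_b, protocol, condition_index, seed=rng, binding_starts=starts,
        return_details=True,
    )
    h, w = protocol.field_shape
    details["x_px"] = rng.uniform(margin_px, w - 1 - margin_px, size=n_molecules)
    details["y_px"] = rng.uniform(margin_px, h - 1 - margin_px, size=n_molecules)
    details["condition_index"] = condition_index
    details["molecule_id"] = np.arange(n_molecules)
    visible = details[details["observed_n_frames"] > 0].reset_index(drop=True)
    return visible[GROUND_TRUTH_COLUMNS]


def simulate_dwell_dataset(
    model: KineticModel,
    protocol: AcquisitionProtocol,
    n_per_condition: int,
    seed=None,
) -> dict[int, np.ndarray]:
    """Apparent dwell times (seconds) per condition, skipping rendering.

    Events bind at frame boundaries; zero-frame events are dropped.  This
    is the fast path for fitting experiments where the imaging stages are
    not under test.
    """
    rng = _rng(seed)
    out = {}
    for ci in range(protocol.n_conditions):
        durations = sample_dwell_times(model, n_per_condition, seed=rng)
        frames = simulate_observed_frames(durations, model.k_b, protocol, ci, seed=rng)
        out[ci] = frames * protocol.tau_tl(ci)
    return out


def score_detections(
    foci: pd.DataFrame,
    truth_events: pd.DataFrame,
    protocol: AcquisitionProtocol,
    tol_px: float = 1.0,
) -> dict:
    """Recall/precision of a foci table against ground-truth events.

    A detected focus is a true positive if it lies within ``tol_px`` of a
    ground-truth molecule visible in the same frame (foci use absolute
    frame indices, ground truth uses phase-II indices).
    """
    per_frame: dict[int, list] = {}
    total = 0
    for row in truth_events.itertuples(index=False):
        for f in range(int(row.observed_first_frame),
                       int(row.observed_first_frame) + int(row.observed_n_frames)):
            per_frame.setdefault(f + protocol.n_bleach_frames, []).append(
                (float(row.x_px), float(row.y_px))
            )
            total += 1
    tp = fp = 0
    for row in foci.itertuples(index=False):
        cands = per_frame.get(int(row.frame), [])
        if any(np.hypot(row.x_px - x, row.y_px - y) <= tol_px for x, y in cands):
            tp += 1
        else:
            fp += 1
    return {
        "n_truth": total,
        "n_detected": int(len(foci)),
        "recall": tp / total if total else np.nan,
        "precision": tp / (tp + fp) if (tp + fp) else np.nan,
    }


@dataclass
class MovieStack:
    """Rendered movie with its acquisition metadata and noise parameters."""

    data: np.ndarray  # (n_total_frames, height, width), counts >= 0
    protocol: AcquisitionProtocol
    condition_index: int
    psf_sigma_px: float
    spot_amplitude: float
    background: float
    camera_offset: float
    read_noise: float

    def __post_init__(self) -> None:
        expected = self.protocol.n_total_frames
        if self.data.shape[0] != expected:
            raise ValueError(
                f"stack has {self.data.shape[0]} frames, protocol requires {expected}"
            )
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def phase2(self) -> np.ndarray:
        return self.data[self.protocol.n_bleach_frames:]

    def noise_dict(self) -> dict:
        return {
            "psf_sigma_px": self.psf_sigma_px,
            "spot_amplitude": self.spot_amplitude,
            "background": self.background,
            "camera_offset": self.camera_offset,
            "read_noise": self.read_noise,
        }


def _stamp_gaussian(image: np.ndarray, x: float, y: float, sigma: float, flux: float) -> None:
    """Add a 2-D Gaussian of integrated intensity ``flux`` centred at (x, y)."""
    h, w = image.shape
    r = max(3, int(np.ceil(4 * sigma)))
    x0, y0 = int(round(x)), int(round(y))
    xs = np.arange(max(0, x0 - r), min(w, x0 + r + 1))
    ys = np.arange(max(0, y0 - r), min(h, y0 + r + 1))
    if xs.size == 0 or ys.size == 0:
        return
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
    image[np.ix_(ys, xs)] += flux / (2 * np.pi * sigma**2) * np.outer(gy, gx)


def render_movie(
    events: pd.DataFrame,
    protocol: AcquisitionProtocol,
    condition_index: int,
    psf_sigma_px: float = 1.2,
    spot_amplitude: float = 800.0,
    background: float = 20.0,
    camera_offset: float = 100.0,
    read_noise: float = 2.0,
    n_phase1_emitters: int | None = None,
    seed=None,
) -> MovieStack:
    """Render a two-phase movie from a ground-truth event table.

    Each visible molecule contributes a static symmetric Gaussian spot of
    integrated intensity ``spot_amplitude`` in every frame of its observed
    span.  Pixel values are Poisson counts of (background + spots) plus a
    camera offset and Gaussian read noise.  Phase-I frames carry a decaying
    pool of extra emitters that mimics the bleach-down; it is cosmetic and
    never enters the ground truth.
    """
    if psf_sigma_px <= 0 or spot_amplitude <= 0:
        raise ValueError("psf_sigma_px and spot_amplitude must be positive")
    if background < 0 or read_noise < 0:
        raise ValueError("background and read_noise must be non-negative")
    protocol._check_condition(condition_index)
    h, w = protocol.field_shape
    if len(events):
        if (events["x_px"].min() < 0 or events["x_px"].max() > w - 1
                or events["y_px"].min() < 0 or events["y_px"].max() > h - 1):
            raise ValueError("event positions fall outside the field bounds")
    rng = _rng(seed)
    n_total = protocol.n_total_frames
    n_bleach = protocol.n_bleach_frames
    signal = np.full((n_total, h, w), float(background))

    # Phase I: cosmetic bleach-down pool, ~10-frame mean survival.
    if n_phase1_emitters is None:
        n_phase1_emitters = 3 * len(events)
    if n_bleach > 0 and n_phase1_emitters > 0:
        px = rng.uniform(0, w - 1, size=n_phase1_emitters)
        py = rng.uniform(0, h - 1, size=n_phase1_emitters)
        survive = rng.geometric(p=0.1, size=n_phase1_emitters)
        for x, y, s in zip(px, py, survive):
            for f in range(min(int(s), n_bleach)):
                _stamp_gaussian(signal[f], x, y, psf_sigma_px, spot_amplitude)

    # Phase II: ground-truth events.
    for row in events.itertuples(index=False):
        f0 = n_bleach + int(row.observed_first_frame)
        for f in range(f0, f0 + int(row.observed_n_frames)):
            _stamp_gaussian(signal[f], float(row.x_px), float(row.y_px),
                            psf_sigma_px, spot_amplitude)

    data = rng.poisson(signal).astype(np.float32)
    data += camera_offset
    if read_noise > 0:
        data += rng.normal(0.0, read_noise, size=data.shape).astype(np.float32)
    np.clip(data, 0, None, out=data)
    return MovieStack(
        data=data,
        protocol=protocol,
        condition_index=condition_index,
        psf_sigma_px=psf_sigma_px,
        spot_amplitude=spot_amplitude,
        background=background,
        camera_offset=camera_offset,
        read_noise=read_noise,
    )


def make_fixture_dataset(
    model: KineticModel,
    protocol: AcquisitionProtocol,
    n_molecules_per_condition: int,
    outdir,
    seed: int = 0,
    mode: str = "movies",
    render_kwargs: Mapping | None = None,
) -> dict:
    """Write a complete synthetic dataset: one movie (or dwell table) per
    dark-interval condition plus a global ground-truth table.

    ``mode="movies"`` writes multi-page TIFFs with YAML metadata sidecars;
    ``mode="dwells"`` skips rendering and writes per-condition dwell CSVs
    only.  Per-condition seeds are derived deterministically from ``seed``
    and the condition index.  Returns a manifest of the written paths.
    """
    from . import io as dkio  # local import: io depends on simulate types

    if mode not in {"movies", "dwells"}:
        raise ValueError(f"unknown mode {mode!r}")
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    render_kwargs = dict(render_kwargs or {})
    manifest: dict = {"mode": mode, "seed": seed, "conditions": {}}
    truth_tables = []
    for ci in range(protocol.n_conditions):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), ci]))
        events = simulate_events(model, protocol, ci, n_molecules_per_condition, seed=rng)
        truth_tables.append(events)
        entry: dict = {"n_events": int(len(events))}
        tau_tl = protocol.tau_tl(ci)
        dwells = pd.DataFrame(
            {
                "condition_id": ci,
                "n_frames": events["observed_n_frames"].to_numpy(),
                "dwell_s": events["observed_n_frames"].to_numpy() * tau_tl,
                "censored": events["censored"].to_numpy(),
            }
        )
        dwell_path = outdir / f"dwells_cond{ci:02d}.csv"
        dwells.to_csv(dwell_path, index=False)
        entry["dwells"] = str(dwell_path)
        if mode == "movies":
            movie = render_movie(events, protocol, ci, seed=rng, **render_kwargs)
            tif = outdir / f"cond{ci:02d}.tif"
            dkio.write_movie(tif, movie)
            entry["movie"] = str(tif)
            entry["metadata"] = str(tif.with_suffix(".yaml"))
        manifest["conditions"][ci] = entry
    truth = pd.concat(truth_tables, ignore_index=True)
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    manifest["ground_truth"] = str(truth_path)
    return manifest
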