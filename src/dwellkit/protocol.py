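"""Acquisition protocols and dissociation-kinetics models.

Interval (time-lapse) imaging acquires fixed illuminated exposures of
duration ``tau_int`` separated by a dark interval ``tau_d``, so that the
frame period is ``tau_tl = tau_int + tau_d``.  Photobleaching advances only
while the light is on (proportional to ``tau_int`` per frame) whereas
dissociation advances in real time (proportional to ``tau_tl``), which is
what lets a series of ``tau_d`` conditions separate the photobleaching rate
``k_b`` from the dissociation rate(s) ``k_off``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_TAU_D",
    "AcquisitionProtocol",
    "KineticModel",
]

#: Default dark-interval schedule in seconds.  ``0.0`` encodes continuous
#: imaging; the remaining ten values span three orders of magnitude of
#: frame period when combined with the 0.1-s exposure.
DEFAULT_TAU_D: tuple[float, ...] = (
    0.0, 0.1, 0.2, 0.3, 0.5, 0.9, 1.9, 2.9, 4.9, 7.9, 9.9,
)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Exposure/dark-interval schedule and camera geometry for one experiment.

    Parameters
    ----------
    tau_int : float
        Illuminated exposure per frame, seconds.
    tau_d_list : tuple of float
        Dark interval per condition, seconds; ``0`` encodes continuous
        imaging.  One movie is acquired per condition.
    n_bleach_frames : int
        Frames in the continuous bleach-down phase (phase I) that precedes
        single-molecule acquisition.
    n_frames : int
        Frames in the single-molecule phase (phase II).
    pixel_size_nm : float
        Physical pixel size of the camera, nanometres.
    field_shape : (int, int)
        Image height x width in pixels.
    """

    tau_int: float = 0.1
    tau_d_list: tuple[float, ...] = DEFAULT_TAU_D
    n_bleach_frames: int = 50
    n_frames: int = 100
    pixel_size_nm: float = 106.0
    field_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_d_list", tuple(float(d) for d in self.tau_d_list))
        object.__setattr__(self, "field_shape", tuple(int(s) for s in self.field_shape))
        if not self.tau_int > 0:
            raise ValueError(f"tau_int must be positive, got {self.tau_int}")
        if len(self.tau_d_list) == 0:
            raise ValueError("tau_d_list must contain at least one condition")
        if any(d < 0 for d in self.tau_d_list):
            raise ValueError("dark intervals must be non-negative")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.n_bleach_frames < 0:
            raise ValueError("n_bleach_frames must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if len(self.field_shape) != 2 or any(s < 1 for s in self.field_shape):
            raise ValueError(f"field_shape must be (height, width), got {self.field_shape}")

    # -- condition arithmetic -------------------------------------------------

    @property
    def n_conditions(self) -> int:
        return len(self.tau_d_list)

    @property
    def n_total_frames(self) -> int:
        """Frames per movie: bleach-down phase plus single-molecule phase."""
        return self.n_bleach_frames + self.n_frames

    def tau_d(self, condition_index: int) -> float:
        self._check_condition(condition_index)
        return self.tau_d_list[condition_index]

    def tau_tl(self, condition_index: int) -> float:
        """Frame period ``tau_int + tau_d`` for one condition, seconds."""
        return self.tau_int + self.tau_d(condition_index)

    def tau_tl_all(self) -> np.ndarray:
        return np.asarray([self.tau_int + d for d in self.tau_d_list])

    def phase2_duration(self, condition_index: int) -> float:
        """Real-time span of the single-molecule phase, seconds."""
        return self.n_frames * self.tau_tl(condition_index)

    def _check_condition(self, condition_index: int) -> None:
        if not 0 <= int(condition_index) < self.n_conditions:
            raise IndexError(
                f"condition_index {condition_index} out of range "
                f"[0, {self.n_conditions})"
            )

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tau_int": self.tau_int,
            "tau_d_list": list(self.tau_d_list),
            "n_bleach_frames": self.n_bleach_frames,
            "n_frames": self.n_frames,
            "pixel_size_nm": self.pixel_size_nm,
            "field_shape": list(self.field_shape),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionProtocol":
        return cls(
            tau_int=float(d["tau_int"]),
            tau_d_list=tuple(d["tau_d_list"]),
            n_bleach_frames=int(d["n_bleach_frames"]),
            n_frames=int(d["n_frames"]),
            pixel_size_nm=float(d.get("pixel_size_nm", 106.0)),
            field_shape=tuple(d.get("field_shape", (512, 512))),
        )


@dataclass(frozen=True)
class KineticModel:
    """Exponential-mixture dissociation model plus photobleaching rate.

    ``components`` is a sequence of ``(amplitude, k_off)`` pairs; amplitudes
    are strictly positive and sum to one, rates are per second.  ``k_b`` is
    the photobleaching rate, applied only while the molecule is illuminated.
    One or two components are supported (single- or bi-exponential binding).
    """

    components: tuple[tuple[float, float], ...]
    k_b: float = 0.0

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(k)) for a, k in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise ValueError(f"1 or 2 components supported, got {len(comps)}")
        amps = np.array([a for a, _ in comps])
        rates = np.array([k for _, k in comps])
        if np.any(amps <= 0):
            raise ValueError(f"amplitudes must be strictly positive, got {amps}")
        if abs(amps.sum() - 1.0) > 1e-12:
            raise ValueError(f"amplitudes must sum to 1 (+-1e-12), got sum {amps.sum()!r}")
        if np.any(rates < 0) or self.k_b < 0:
            raise ValueError("all rates must be non-negative")

    @classmethod
    def from_lifetimes(
        cls,
        lifetimes_s: Sequence[float] | float,
        fractions: Sequence[float] | None = None,
        k_b: float = 0.0,
    ) -> "KineticModel":
        """Build a model from bound lifetimes (1/k_off) and their fractions."""
        lifetimes = np.atleast_1d(np.asarray(lifetimes_s, dtype=float))
        if fractions is None:
            if lifetimes.size != 1:
                raise ValueError("fractions required for more than one lifetime")
            fractions = [1.0]
        fractions = np.asarray(fractions, dtype=float)
        if fractions.shape != lifetimes.shape:
            raise ValueError("lifetimes and fractions must have equal length")
        with np.errstate(divide="ignore"):
            rates = np.where(lifetimes > 0, 1.0 / lifetimes, np.inf)
        if np.any(~np.isfinite(rates)):
            raise ValueError("lifetimes must be positive and finite")
        return cls(tuple(zip(fractions, rates)), k_b=k_b)

    # -- views ---------------------------------------------------------------

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def k_offs(self) -> np.ndarray:
        return np.array([k for _, k in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        """Bound lifetimes 1/k_off, seconds (inf for k_off = 0)."""
        with np.errstate(divide="ignore"):
            return np.where(self.k_offs > 0, 1.0 / self.k_offs, np.inf)

    def mixture_cdf(self, t) -> np.ndarray:
        """P(bound duration <= t) for the amplitude-weighted mixture."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, k in self.components:
            out = out + a * (1.0 - np.exp(-k * t))
        return out

    def mixture_mean(self) -> float:
        """Mean bound duration, seconds (inf if any component never unbinds)."""
        return float(np.sum(self.amplitudes * self.lifetimes))

    def to_dict(self) -> dict:
        return {
            "components": [list(c) for c in self.components],
            "k_b": self.k_b,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticModel":
        return cls(tuple(tuple(c) for c in d["components"]), k_b=float(d["k_b"]))
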