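"""Domain types, configuration schema and seeded random-stream management.

All lengths are millimetres internally; ``mua``, ``mus`` and ``mut`` are in
mm^-1 and angles in radians.  Config files use explicitly unit-suffixed keys
(``beam.w0_um``, ``medium.mua_per_mm``, ``detection.theta_max_deg``, ...) so
that every number matches the convention OCT practitioners print.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "BeamGeometry",
    "OpticalMedium",
    "DetectionConfig",
    "SimulationConfig",
    "critical_angle",
    "make_rng_stream",
    "kernel_seed",
    "load_config",
    "save_config",
]

MODELS = ("conventional", "hybrid")

#: Default cutoff on the surface-incidence angle (radians).  An air/water
#: interface (n = 1.33) has a critical angle for total internal reflection of
#: arcsin(1/1.33) = 48.75 deg; the simulation rounds this up to a 50 deg
#: acceptance cutoff.  Photons hitting the surface at larger angles are
#: discarded (no re-entry), which also keeps the attenuation-adjustment
#: factor of the hybrid model bounded.
DEFAULT_THETA_MAX = math.radians(50.0)


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclasses.dataclass(frozen=True)
class BeamGeometry:
    """Focused Gaussian illumination/detection mode inside the sample.

    Parameters
    ----------
    w0 : float
        Beam-waist radius in mm (1/e^2 intensity radius).
    zR : float
        Rayleigh range in the medium, mm.
    zf : float
        Focus depth below the sample surface, mm.
    """

    w0: float
    zR: float
    zf: float

    def __post_init__(self) -> None:
        _positive("w0", self.w0)
        _positive("zR", self.zR)
        if self.zf < 0:
            raise ValueError(f"zf must be >= 0, got {self.zf!r}")

    @property
    def theta_div(self) -> float:
        """Divergence angle of the Gaussian beam, ``w0 / zR`` (radians)."""
        return self.w0 / self.zR

    def width(self, z_prime: float | np.ndarray) -> float | np.ndarray:
        """1/e^2 beam radius ``w(z') = w0 sqrt(1 + (z'/zR)^2)`` at axial
        distance ``z'`` from the focus."""
        return self.w0 * np.sqrt(1.0 + (np.asarray(z_prime) / self.zR) ** 2)


@dataclasses.dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous turbid medium: absorption, scattering, anisotropy, index."""

    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua!r}")
        if self.mus < 0:
            raise ValueError(f"mus must be >= 0, got {self.mus!r}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must be in (-1, 1), got {self.g!r}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n!r}")

    @property
    def mut(self) -> float:
        """Attenuation coefficient ``mua + mus`` (mm^-1)."""
        return self.mua + self.mus


@dataclasses.dataclass(frozen=True)
class DetectionConfig:
    """Coherence gate and detection-model settings.

    ``lc`` is the one-way optical-pathlength bin resolution (the coherence
    length of the source, 4 um by default).  ``n_bins`` one-way OPL bins span
    physical depths 0 .. n_bins*lc/n; the default 1330 covers 0-4 mm at
    n = 1.33.  ``theta_max`` is the surface-incidence cutoff.
    """

    lc: float = 4e-3
    n_bins: int = 1330
    theta_max: float = DEFAULT_THETA_MAX
    model: str = "hybrid"
    weight_cutoff: float = 1e-6

    def __post_init__(self) -> None:
        _positive("lc", self.lc)
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins!r}")
        if not 0.0 < self.theta_max <= math.pi / 2:
            raise ValueError(f"theta_max must be in (0, pi/2], got {self.theta_max!r}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not 0.0 <= self.weight_cutoff < 1.0:
            raise ValueError(f"weight_cutoff must be in [0, 1), got {self.weight_cutoff!r}")

    @property
    def max_opl(self) -> float:
        """Round-trip OPL at which a packet is terminated.

        A packet whose accumulated OPL already exceeds the largest binnable
        round-trip OPL (2*n_bins*lc) cannot contribute to any bin; a 1.5x
        safety factor leaves headroom for the hybrid model's pathlength
        correction while keeping the truncation unbiased for the window.
        """
        return 3.0 * self.n_bins * self.lc


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    beam: BeamGeometry
    medium: OpticalMedium
    detection: DetectionConfig
    n_photons: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError(f"n_photons must be >= 1, got {self.n_photons!r}")

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "beam": {
                "w0_um": self.beam.w0 * 1e3,
                "zR_um": self.beam.zR * 1e3,
                "zf_mm": self.beam.zf,
            },
            "medium": {
                "mua_per_mm": self.medium.mua,
                "mus_per_mm": self.medium.mus,
                "g": self.medium.g,
                "n": self.medium.n,
            },
            "detection": {
                "lc_um": self.detection.lc * 1e3,
                "n_bins": self.detection.n_bins,
                "theta_max_deg": math.degrees(self.detection.theta_max),
                "model": self.detection.model,
                "weight_cutoff": self.detection.weight_cutoff,
            },
            "n_photons": int(self.n_photons),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        try:
            beam = BeamGeometry(
                w0=float(d["beam"]["w0_um"]) * 1e-3,
                zR=float(d["beam"]["zR_um"]) * 1e-3,
                zf=float(d["beam"]["zf_mm"]),
            )
            med = d["medium"]
            medium = OpticalMedium(
                mua=float(med["mua_per_mm"]),
                mus=float(med["mus_per_mm"]),
                g=float(med["g"]),
                n=float(med["n"]),
            )
            det = d.get("detection", {})
            detection = DetectionConfig(
                lc=float(det.get("lc_um", 4.0)) * 1e-3,
                n_bins=int(det.get("n_bins", 1330)),
                theta_max=math.radians(float(det.get("theta_max_deg", 50.0))),
                model=str(det.get("model", "hybrid")),
                weight_cutoff=float(det.get("weight_cutoff", 1e-6)),
            )
            return cls(
                beam=beam,
                medium=medium,
                detection=detection,
                n_photons=int(d["n_photons"]),
                seed=int(d["seed"]),
            )
        except KeyError as exc:
            raise ValueError(f"missing config key: {exc}") from exc


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def critical_angle(n_medium: float, n_outside: float = 1.0) -> float:
    """Critical angle for total internal reflection, ``arcsin(n_out/n_med)``.

    For water-like tissue against air (n = 1.33) this is 48.75 deg, commonly
    quoted as 49 deg.
    """
    if not 0.0 < n_outside <= n_medium:
        raise ValueError(
            "total internal reflection requires 0 < n_outside <= n_medium, "
            f"got n_medium={n_medium!r}, n_outside={n_outside!r}"
        )
    return math.asin(n_outside / n_medium)


def make_rng_stream(seed: int, stream_id: int = 0) -> np.random.Generator:
    """Independent, reproducible random stream for (seed, stream_id).

    Streams with different ``stream_id`` under the same ``seed`` (or the
    same ``stream_id`` under different seeds) are statistically independent;
    the same pair always yields the same sequence.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream_id,))
    return np.random.Generator(np.random.PCG64(ss))


def kernel_seed(seed: int, stream_id: int = 0) -> int:
    """32-bit seed for the compiled transport kernel, derived so that
    distinct (seed, stream_id) pairs give independent kernel streams."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream_id,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])
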