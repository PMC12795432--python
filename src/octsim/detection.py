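"""Coherence-gated detection: photon records -> depth profiles.

Two detection models convert a backscattered packet into a detected
intensity:

* ``conventional`` — the packet couples into the single-mode-fiber (SMF)
  Gaussian mode with an amplitude position weight (Gaussian in lateral
  offset, evaluated on the mode-waist plane reached by extending the exit
  ray as a straight line) and an amplitude direction weight (Gaussian in
  the lateral direction components over the divergence angle).
* ``hybrid`` — the packet is replaced by a spherical wave from its last
  scatter position: detected intensity is the exit weight times the surface
  flux projection cos(theta_i), the analytic power coupling T of a
  spherical wave into the Gaussian mode, and an attenuation adjustment
  Padj >= 1 converting the sampled oblique exit path's survival probability
  to that of the shortest (vertical) path.  The exit-leg OPL is likewise
  replaced by the vertical OPL, shifting the packet to a shallower bin.

Detected intensities are summed incoherently per one-way OPL bin of width
``lc``; bin j maps to physical depth ``j * lc / n``.

All weight functions are vectorized over record arrays.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Any, Optional

import numpy as np
import pandas as pd

from .core import BeamGeometry, DetectionConfig, OpticalMedium
from .transport import PhotonRecords

__all__ = [
    "DepthProfile",
    "position_weight",
    "direction_weight",
    "detect_conventional",
    "transmission_T",
    "attenuation_adjustment",
    "detect_hybrid",
    "corrected_opl",
    "assign_bin",
    "accumulate_profile",
]


@dataclasses.dataclass
class DepthProfile:
    """Coherence-gated intensity versus one-way OPL bin / physical depth.

    ``intensity_sq`` carries the per-bin sum of squared detected
    intensities, whose square root estimates the one-sigma Monte Carlo
    error on ``intensity`` (compound-Poisson variance estimator).
    """

    bin_index: np.ndarray
    opl_depth: np.ndarray       # j * lc, mm
    physical_depth: np.ndarray  # j * lc / n, mm
    intensity: np.ndarray
    intensity_sq: np.ndarray
    n_contributing: np.ndarray
    model: Optional[str] = None
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return self.bin_index.shape[0]

    @property
    def error(self) -> np.ndarray:
        """One-sigma Monte Carlo error estimate per bin."""
        return np.sqrt(self.intensity_sq)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": self.bin_index,
            "opl_depth_um": self.opl_depth * 1e3,
            "depth_um": self.physical_depth * 1e3,
            "intensity": self.intensity,
            "intensity_sq": self.intensity_sq,
            "n_photons": self.n_contributing,
        })

    @classmethod
    def empty(cls, detection: DetectionConfig, n: float,
              model: Optional[str] = None) -> "DepthProfile":
        j = np.arange(detection.n_bins)
        return cls(
            bin_index=j,
            opl_depth=j * detection.lc,
            physical_depth=j * detection.lc / n,
            intensity=np.zeros(detection.n_bins),
            intensity_sq=np.zeros(detection.n_bins),
            n_contributing=np.zeros(detection.n_bins, dtype=np.int64),
            model=model,
        )


# ---------------------------------------------------------------------------
# conventional model
# ---------------------------------------------------------------------------

def position_weight(x, y, w0: float):
    """Amplitude position weight ``exp(-(x^2+y^2)/w0^2)`` of a photon on
    the SMF mode surface."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.exp(-(x * x + y * y) / (w0 * w0))


def direction_weight(vx, vy, theta_div: float):
    """Amplitude direction weight ``exp(-(vx^2+vy^2)/theta_div^2)``: the
    plane-wave coupling of an obliquely incident photon with the Gaussian
    mode of divergence angle ``theta_div = w0/zR``."""
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    return np.exp(-(vx * vx + vy * vy) / (theta_div * theta_div))


def detect_conventional(records: PhotonRecords, beam: BeamGeometry):
    """Detected intensity of each record under the conventional model.

    The SMF acts as both source and detector, so the mode imaged into the
    sample is the illumination Gaussian itself: coupling is evaluated in
    sample space by extending the exit ray as a straight line to the
    mode-waist plane z = zf (the etendue-preserving equivalent of
    propagating to the fiber facet through ideal imaging optics) and
    weighting position there and direction at the surface.
    """
    t = beam.zf / records.vz          # vz < 0: extension through the medium
    xr = records.exit_x + records.vx * t
    yr = records.exit_y + records.vy * t
    return (records.weight
            * position_weight(xr, yr, beam.w0)
            * direction_weight(records.vx, records.vy, beam.theta_div))


# ---------------------------------------------------------------------------
# hybrid particle-wave model
# ---------------------------------------------------------------------------

def transmission_T(x, y, z_prime, beam: BeamGeometry):
    """Power coupling of a spherical wave from (x, y, zf + z') into the
    Gaussian mode:
    ``T = (w0/zR)^2 (w0/w(z'))^2 exp(-2 (x^2+y^2) / w(z')^2)``,
    maximal on axis at the focus, where it equals ``(w0/zR)^2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wz2 = np.asarray(beam.width(z_prime)) ** 2
    return ((beam.w0 / beam.zR) ** 2 * (beam.w0 ** 2 / wz2)
            * np.exp(-2.0 * (x * x + y * y) / wz2))


def attenuation_adjustment(mut: float, z, theta):
    """Attenuation adjustment ``Padj = exp(mut * z * (1/cos(theta) - 1))``.

    Ratio of the survival probability along the shortest (vertical) path
    from the last scatter depth ``z`` to that along the sampled oblique
    exit path; always >= 1.  Computed in log space; diverges as theta
    approaches 90 deg, which the acceptance cutoff keeps out of range.
    """
    z = np.asarray(z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta >= math.pi / 2):
        raise ValueError("Padj diverges for theta >= 90 deg")
    log_p = mut * z * (1.0 / np.cos(theta) - 1.0)
    return np.exp(log_p)


def detect_hybrid(records: PhotonRecords, beam: BeamGeometry,
                  medium: OpticalMedium):
    """Detected intensity of each record under the hybrid model:
    ``I_i cos(theta_i) T(x_i, y_i, z_i - zf) Padj``."""
    cos_ti = np.cos(records.theta_i)
    trans = transmission_T(records.lsx, records.lsy,
                           records.lsz - beam.zf, beam)
    padj = attenuation_adjustment(medium.mut, records.lsz, records.theta_i)
    return records.weight * cos_ti * trans * padj


def corrected_opl(li, n: float, zi, theta_i):
    """Round-trip OPL with the exit leg replaced by the vertical path from
    the last scatter depth: ``l' = l + n z (1 - 1/cos(theta))``; always
    <= l, with equality only at normal exit."""
    li = np.asarray(li, dtype=float)
    zi = np.asarray(zi, dtype=float)
    theta_i = np.asarray(theta_i, dtype=float)
    return li + n * zi * (1.0 - 1.0 / np.cos(theta_i))


# ---------------------------------------------------------------------------
# binning and accumulation
# ---------------------------------------------------------------------------

def assign_bin(l, lc: float):
    """One-way OPL bin of a round-trip OPL ``l``: the bin whose centre
    ``j*lc`` is within lc/2 of ``l/2``, with exact boundaries assigned
    upward (half-open convention)."""
    l = np.asarray(l, dtype=float)
    return np.floor(l / (2.0 * lc) + 0.5).astype(np.int64)


def accumulate_profile(records: PhotonRecords, model: str,
                       beam: BeamGeometry, medium: OpticalMedium,
                       detection: DetectionConfig) -> DepthProfile:
    """Sum detected intensities per OPL bin into a depth profile.

    The conventional model bins on the simulated round-trip OPL; the hybrid
    model bins on the corrected OPL of the spherical-wave picture.
    """
    profile = DepthProfile.empty(detection, medium.n, model=model)
    if len(records) == 0:
        return profile
    if model == "conventional":
        intensity = detect_conventional(records, beam)
        opl = records.opl_total
    elif model == "hybrid":
        intensity = detect_hybrid(records, beam, medium)
        opl = corrected_opl(records.opl_total, medium.n,
                            records.lsz, records.theta_i)
    else:
        raise ValueError(f"unknown detection model {model!r}")
    j = assign_bin(opl, detection.lc)
    ok = (j >= 0) & (j < detection.n_bins)
    j = j[ok]
    intensity = intensity[ok]
    nb = detection.n_bins
    profile.intensity = np.bincount(j, weights=intensity, minlength=nb)
    profile.intensity_sq = np.bincount(j, weights=intensity ** 2, minlength=nb)
    profile.n_contributing = np.bincount(j, minlength=nb).astype(np.int64)
    return profile
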