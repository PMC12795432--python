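"""Single-scatter OCT theory, fitting and profile comparison.

The single-scatter model of a focused-beam OCT depth profile in a
homogeneous medium is a confocal Lorentzian times Lambert-Beer decay::

    I(z) = A / (1 + ((z - zf)/zR)^2) * exp(-2 mut z)

valid while singly backscattered light dominates.  Amplitude fits against
simulated profiles use a plain L2 norm; fits against (pseudo-)experimental
profiles add a noise floor C and minimise relative residuals
``<[(A I_sim + C)/I_target - 1]^2>`` so that the low-signal tail, where the
noise floor lives, is not swamped by the bright shallow bins.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .detection import DepthProfile

__all__ = [
    "TheoryParams",
    "FitResult",
    "single_scatter_profile",
    "fit_amplitude",
    "fit_with_noise_floor",
    "rmsd",
    "grid_search",
    "GridSearchResult",
]


@dataclasses.dataclass(frozen=True)
class TheoryParams:
    """Parameters of the single-scatter depth-profile model."""
    A: float
    zf: float
    zR: float
    mut: float

    def __post_init__(self) -> None:
        if self.zR <= 0:
            raise ValueError(f"zR must be > 0, got {self.zR!r}")
        if self.mut < 0:
            raise ValueError(f"mut must be >= 0, got {self.mut!r}")


@dataclasses.dataclass
class FitResult:
    A: float
    C: Optional[float] = None
    objective: float = 0.0
    converged: bool = True


def single_scatter_profile(z, params: TheoryParams):
    """Evaluate the confocal-times-Lambert-Beer model on a depth grid."""
    z = np.asarray(z, dtype=float)
    confocal = 1.0 / (1.0 + ((z - params.zf) / params.zR) ** 2)
    return params.A * confocal * np.exp(-2.0 * params.mut * z)


def _window(profile: DepthProfile, exclude_bins: int) -> np.ndarray:
    mask = profile.bin_index >= exclude_bins
    return mask


def fit_amplitude(sim_profile: DepthProfile, params: TheoryParams,
                  exclude_bins: int = 1) -> FitResult:
    """Closed-form least-squares amplitude of the theory model against a
    simulated profile, all other parameters fixed to simulation truth.

    Bin 0 (the surface) is excluded by default.
    """
    mask = _window(sim_profile, exclude_bins)
    z = sim_profile.physical_depth[mask]
    isim = sim_profile.intensity[mask]
    base = single_scatter_profile(z, dataclasses.replace(params, A=1.0))
    denom = float(np.dot(base, base))
    if denom == 0.0:
        raise ValueError("theory profile is identically zero on the window")
    a = float(np.dot(isim, base)) / denom
    resid = isim - a * base
    return FitResult(A=a, objective=float(np.mean(resid ** 2)))


def fit_with_noise_floor(sim_profile: DepthProfile,
                         target_profile: DepthProfile,
                         exclude_bins: int = 1,
                         max_depth: float | None = None) -> FitResult:
    """Fit scale A and noise floor C of a simulated profile to a target.

    The target is linearly interpolated onto the simulation depth grid
    (overlapping depth range only, no extrapolation) and the relative
    residual ``(A I_sim + C)/I_target - 1`` is minimised by weighted linear
    least squares; C is clipped at zero.

    The relative weighting presumes both profiles are smooth; when the
    simulation's photon count leaves the deep tail sparsely populated,
    restrict the fit window with ``max_depth`` (mm) to the depth range
    where the bins are populated.
    """
    mask = _window(sim_profile, exclude_bins)
    if max_depth is not None:
        mask = mask & (sim_profile.physical_depth <= max_depth)
    z = sim_profile.physical_depth[mask]
    isim = sim_profile.intensity[mask]
    zt = target_profile.physical_depth
    it = target_profile.intensity
    if np.any(it <= 0.0):
        raise ValueError("target intensities must be strictly positive")
    overlap = (z >= zt.min()) & (z <= zt.max())
    z, isim = z[overlap], isim[overlap]
    itarg = np.interp(z, zt, it)
    # weighted linear LS: [isim/itarg, 1/itarg] @ (A, C) ~= 1
    design = np.column_stack([isim / itarg, 1.0 / itarg])
    coef, *_ = np.linalg.lstsq(design, np.ones_like(itarg), rcond=None)
    a, c = float(coef[0]), float(coef[1])
    if c < 0.0:
        c = 0.0
        x = isim / itarg
        a = float(np.dot(x, np.ones_like(x)) / np.dot(x, x))
    resid = (a * isim + c) / itarg - 1.0
    return FitResult(A=a, C=c, objective=float(np.mean(resid ** 2)))


def rmsd(profile_a, profile_b) -> float:
    """Root-mean-square deviation between two equal-length intensity grids."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError(f"profiles must have equal nonzero length, "
                         f"got {a.shape} and {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclasses.dataclass
class GridSearchResult:
    best_mus: float
    best_g: float
    table: pd.DataFrame


def grid_search(target_profile: DepthProfile,
                candidates: Sequence[tuple[float, float]],
                base_config, n_photons: int, seed: int,
                exclude_bins: int = 1,
                max_depth: float | None = None,
                simulator: Optional[Callable] = None) -> GridSearchResult:
    """Recover (mus, g) by simulate-fit-RMSD over a candidate grid.

    For every candidate the medium's (mus, g) are substituted into
    ``base_config``, a hybrid-model profile is simulated with ``n_photons``
    and a per-candidate child seed, fitted to the target with scale and
    noise floor, and the RMSD between the fitted simulation and the target
    is recorded.  The argmin wins; ties break on first occurrence.
    """
    import dataclasses as _dc

    from .simulate import simulate_depth_profile

    if len(candidates) == 0:
        raise ValueError("candidate grid is empty")
    if simulator is None:
        simulator = simulate_depth_profile
    rows = []
    best = None
    for idx, (mus, g) in enumerate(candidates):
        medium = _dc.replace(base_config.medium, mus=float(mus), g=float(g))
        # child seed: offset by candidate index for independent runs
        config = base_config.replace(medium=medium, n_photons=int(n_photons),
                                     seed=int(seed) + idx)
        profile = simulator(config, model="hybrid")
        fit = fit_with_noise_floor(profile, target_profile,
                                   exclude_bins=exclude_bins,
                                   max_depth=max_depth)
        mask = profile.bin_index >= exclude_bins
        if max_depth is not None:
            mask = mask & (profile.physical_depth <= max_depth)
        z = profile.physical_depth[mask]
        zt = target_profile.physical_depth
        overlap = (z >= zt.min()) & (z <= zt.max())
        fitted = fit.A * profile.intensity[mask][overlap] + fit.C
        itarg = np.interp(z[overlap], zt, target_profile.intensity)
        value = rmsd(fitted, itarg)
        rows.append({"mus": float(mus), "g": float(g), "A": fit.A,
                     "C": fit.C, "rmsd": value})
        if best is None or value < best[0]:
            best = (value, float(mus), float(g))
    table = pd.DataFrame(rows)
    return GridSearchResult(best_mus=best[1], best_g=best[2], table=table)
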