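"""High-level simulation entry points.

:func:`simulate_profiles` streams photons from the compiled transport
kernel directly into both detection models' depth-profile accumulators in a
single pass, without materialising per-photon records; this is the path for
ground-truth-scale photon counts.  It is numerically equivalent (up to
summation order) to ``run_simulation`` + ``accumulate_profile``.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import _kernel
from .core import SimulationConfig, kernel_seed
from .detection import DepthProfile
from .transport import Counters

__all__ = ["SimulationOutput", "simulate_profiles", "simulate_depth_profile"]


@dataclasses.dataclass
class SimulationOutput:
    profiles: dict[str, DepthProfile]
    counters: Counters
    config: SimulationConfig
    seed: int


def simulate_profiles(config: SimulationConfig,
                      seed: int | None = None) -> SimulationOutput:
    """Run transport once and accumulate conventional and hybrid profiles.

    Deterministic given (config, seed); ``seed`` defaults to the config's.
    """
    if seed is None:
        seed = config.seed
    beam, med, det = config.beam, config.medium, config.detection
    nb = det.n_bins
    conv_i = np.zeros(nb)
    conv_i2 = np.zeros(nb)
    conv_n = np.zeros(nb, dtype=np.int64)
    hyb_i = np.zeros(nb)
    hyb_i2 = np.zeros(nb)
    hyb_n = np.zeros(nb, dtype=np.int64)
    counters_arr = np.zeros(5, dtype=np.int64)
    _kernel.run_batch_profiles(
        config.n_photons, kernel_seed(seed, 0),
        beam.w0, beam.zR, beam.zf,
        med.mua, med.mus, med.g, med.n,
        math.cos(det.theta_max), det.weight_cutoff, det.max_opl,
        det.lc, nb,
        conv_i, conv_i2, conv_n, hyb_i, hyb_i2, hyb_n,
        counters_arr,
    )
    profiles = {}
    for model, (ii, i2, nn) in {
        "conventional": (conv_i, conv_i2, conv_n),
        "hybrid": (hyb_i, hyb_i2, hyb_n),
    }.items():
        p = DepthProfile.empty(det, med.n, model=model)
        p.intensity = ii
        p.intensity_sq = i2
        p.n_contributing = nn
        p.meta = {"seed": int(seed), "n_photons": int(config.n_photons)}
        profiles[model] = p
    counters = Counters(*(int(c) for c in counters_arr))
    return SimulationOutput(profiles=profiles, counters=counters,
                            config=config, seed=int(seed))


def simulate_depth_profile(config: SimulationConfig, model: str | None = None,
                           seed: int | None = None) -> DepthProfile:
    """Depth profile for one detection model (default: the config's)."""
    if model is None:
        model = config.detection.model
    out = simulate_profiles(config, seed=seed)
    if model not in out.profiles:
        raise ValueError(f"unknown detection model {model!r}")
    profile = out.profiles[model]
    profile.meta["counters"] = out.counters.as_dict()
    return profile
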