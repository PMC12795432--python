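"""Packaged simulation scenarios and the pseudo-experiment generator.

The presets encode the published study conditions this package reproduces:
a 1300 nm swept-source OCT system with a single-mode-fiber Gaussian beam of
w0 = 15 um waist and zR = 750 um Rayleigh range in the sample, lc = 4 um
one-way OPL bin resolution, and water-like Intralipid dilution phantoms
(mua = 0.15 mm^-1, n = 1.33 unless stated).  Preset photon counts are the
published ones (10^9-10^11); desk-scale work overrides ``n_photons``.

The experimentally measured Intralipid depth profiles are not public, so
:func:`make_pseudo_experiment` generates a stand-in synthetic target:
simulate a scenario, rescale, add a constant noise floor (shot/thermal
noise analogue) and optional multiplicative noise.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .core import (BeamGeometry, DetectionConfig, OpticalMedium,
                   SimulationConfig, make_rng_stream)
from .detection import DepthProfile
from .simulate import simulate_depth_profile

__all__ = ["Scenario", "SCENARIOS", "get_scenario", "make_pseudo_experiment"]


@dataclasses.dataclass(frozen=True)
class Scenario:
    name: str
    config: SimulationConfig
    provenance: str


_BEAM = dict(w0=15e-3, zR=750e-3)
_DET = DetectionConfig()   # lc = 4 um, 1330 bins (0-4 mm at n = 1.33), 50 deg


def _scenario(name, provenance, *, zf, mua, mus, g, n=1.33, n_photons,
              seed=0, model="hybrid"):
    return Scenario(
        name=name,
        config=SimulationConfig(
            beam=BeamGeometry(zf=zf, **_BEAM),
            medium=OpticalMedium(mua=mua, mus=mus, g=g, n=n),
            detection=dataclasses.replace(_DET, model=model),
            n_photons=n_photons,
            seed=seed,
        ),
        provenance=provenance,
    )


SCENARIOS: dict[str, Scenario] = {s.name: s for s in [
    _scenario(
        "weak-validation",
        "Weakly scattering single-scatter validation medium: mus = 0.25 mm^-1, "
        "mua = 0.15 mm^-1, g = 0.3, focus at 2.57 mm; published run used "
        "1.2e11 photons per detection model.",
        zf=2.57, mua=0.15, mus=0.25, g=0.3, n_photons=120_000_000_000),
    _scenario(
        "strong-validation",
        "More strongly scattering validation medium showing multiple-scatter "
        "departure from single-scatter theory: mus = 3.0 mm^-1, mua = 0.15 "
        "mm^-1, g = 0.3, focus at 2.57 mm; published run used 2.4e9 photons.",
        zf=2.57, mua=0.15, mus=3.0, g=0.3, n_photons=2_400_000_000),
    _scenario(
        "weak-benchmark",
        "Weakly scattering NRMSD-efficiency benchmark medium: mus = 0.1 "
        "mm^-1, mua = 0.1 mm^-1, g = 0.3, focus at 2 mm.",
        zf=2.0, mua=0.1, mus=0.1, g=0.3, n_photons=1_000_000),
    _scenario(
        "strong-benchmark",
        "More strongly scattering NRMSD-efficiency benchmark medium: mus = "
        "3.0 mm^-1, mua = 0.15 mm^-1, g = 0.3, focus at 2 mm.",
        zf=2.0, mua=0.15, mus=3.0, g=0.3, n_photons=1_000_000),
    _scenario(
        "intralipid-I01",
        "Intralipid dilution I01 (0.1 vol% scatterer): mus = 0.1 mm^-1, "
        "g = 0.33, focus at 2.81 mm; published runs used 2e9 photons.",
        zf=2.81, mua=0.15, mus=0.1, g=0.33, n_photons=2_000_000_000),
    _scenario(
        "intralipid-I1",
        "Intralipid dilution I1 (1.4 vol%): mus = 1.0 mm^-1, g = 0.33, "
        "focus at 2.71 mm; published runs used 2e9 photons.",
        zf=2.71, mua=0.15, mus=1.0, g=0.33, n_photons=2_000_000_000),
    _scenario(
        "intralipid-I4",
        "Intralipid dilution I4 (5.7 vol%, dependent scattering): mus = 2.9 "
        "mm^-1, g = 0.3, focus at 2.50 mm; published runs used 2e9 photons.",
        zf=2.50, mua=0.15, mus=2.9, g=0.3, n_photons=2_000_000_000),
    _scenario(
        "intralipid-I10",
        "Intralipid dilution I10 (14.1 vol%, dependent scattering): mus = "
        "4.5 mm^-1, g = 0.24, focus at 2.73 mm; published runs used 2e9 "
        "photons.",
        zf=2.73, mua=0.15, mus=4.5, g=0.24, n_photons=2_000_000_000),
]}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


def make_pseudo_experiment(config: SimulationConfig,
                           noise_floor: float,
                           scale: float = 1.0,
                           noise_sigma: float = 0.0,
                           seed: int = 0,
                           model: str = "hybrid") -> DepthProfile:
    """Synthetic stand-in for an experimentally measured depth profile.

    Simulates ``config`` with the given detection model and returns
    ``scale * I_sim + noise_floor``, optionally with multiplicative
    Gaussian noise of relative width ``noise_sigma`` (clipped positive) —
    the constant floor emulates the shot/thermal noise floor of a real
    instrument.  The result is synthetic: it reproduces the coherence-gated
    signal and noise floor but not speckle, specular surface reflection or
    detector roll-off.
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    profile = simulate_depth_profile(config, model=model)
    intensity = scale * profile.intensity + noise_floor
    if noise_sigma > 0.0:
        rng = make_rng_stream(seed, 0)
        factor = 1.0 + noise_sigma * rng.standard_normal(intensity.shape)
        intensity = intensity * np.clip(factor, 0.05, None)
    target = dataclasses.replace(
        profile,
        intensity=intensity,
        intensity_sq=(scale ** 2) * profile.intensity_sq,
        meta={**profile.meta, "pseudo_experiment": {
            "scale": scale, "noise_floor": noise_floor,
            "noise_sigma": noise_sigma, "seed": int(seed)}},
    )
    return target
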