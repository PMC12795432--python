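"""Monte Carlo photon-packet transport in a homogeneous turbid half-space.

The sample occupies z >= 0 with the surface at z = 0.  Packets are launched
at the surface along the straight rulings of the Gaussian beam's
constant-intensity hyperboloid, take exponentially distributed free paths,
scatter with a Henyey-Greenstein phase function, and lose weight
continuously to absorption.  Optical pathlength accumulates as
``n * geometric pathlength`` (constant refractive index).  A packet that
crosses the surface moving upward after at least one scatter is recorded
with its exit weight, lateral position, direction, incidence angle,
round-trip OPL and last-scatter position; packets steeper than the
acceptance cutoff are discarded (no reflection back into the medium).

Two execution paths exist on purpose:

* :func:`run_photon` / :func:`run_simulation_reference` — a plain-Python
  readable reference implementation, one independent random stream per
  photon, used as cross-check at small N.
* :func:`run_simulation` — the compiled batch kernel, statistically
  equivalent, for production photon counts.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import _kernel
from .core import BeamGeometry, SimulationConfig, kernel_seed, make_rng_stream

__all__ = [
    "PhotonState",
    "PhotonRecord",
    "PhotonRecords",
    "Counters",
    "TransportResult",
    "sample_launch",
    "sample_step",
    "sample_hg",
    "rotate_direction",
    "attenuate",
    "run_photon",
    "run_simulation",
    "run_simulation_reference",
]

RECORD_COLUMNS = (
    "weight", "exit_x", "exit_y", "vx", "vy", "vz",
    "theta_i", "opl_total", "lsx", "lsy", "lsz", "n_scatters",
)


@dataclasses.dataclass
class PhotonState:
    position: np.ndarray          # (x, y, z), mm
    direction: np.ndarray         # unit vector
    weight: float = 1.0
    opl: float = 0.0              # accumulated OPL, mm
    last_scatter: Optional[np.ndarray] = None
    n_scatters: int = 0


@dataclasses.dataclass(frozen=True)
class PhotonRecord:
    """Exit state of one backscattered packet."""
    weight: float
    exit_x: float
    exit_y: float
    vx: float
    vy: float
    vz: float
    theta_i: float
    opl_total: float
    lsx: float
    lsy: float
    lsz: float
    n_scatters: int


@dataclasses.dataclass
class PhotonRecords:
    """Struct-of-arrays batch of exit records (the transport/detection
    interchange surface)."""
    weight: np.ndarray
    exit_x: np.ndarray
    exit_y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    theta_i: np.ndarray
    opl_total: np.ndarray
    lsx: np.ndarray
    lsy: np.ndarray
    lsz: np.ndarray
    n_scatters: np.ndarray

    def __len__(self) -> int:
        return self.weight.shape[0]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PhotonRecords":
        return cls(**{name: np.ascontiguousarray(arr[:, i])
                      for i, name in enumerate(RECORD_COLUMNS)})

    @classmethod
    def from_records(cls, records: Iterable[PhotonRecord]) -> "PhotonRecords":
        rows = [[getattr(r, name) for name in RECORD_COLUMNS] for r in records]
        arr = np.asarray(rows, dtype=float).reshape(-1, len(RECORD_COLUMNS))
        return cls.from_array(arr)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({name: getattr(self, name) for name in RECORD_COLUMNS})


@dataclasses.dataclass
class Counters:
    """Per-run packet bookkeeping; launched is conserved across outcomes."""
    launched: int = 0
    recorded: int = 0
    discarded_angle: int = 0
    terminated_weight: int = 0
    terminated_opl: int = 0

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)

    @property
    def conserved(self) -> bool:
        return self.launched == (self.recorded + self.discarded_angle
                                 + self.terminated_weight + self.terminated_opl)


@dataclasses.dataclass
class TransportResult:
    records: PhotonRecords
    counters: Counters


# ---------------------------------------------------------------------------
# elementary sampling operations (reference path)
# ---------------------------------------------------------------------------

def sample_launch(beam: BeamGeometry, rng: np.random.Generator) -> PhotonState:
    """Launch one packet at the surface along a ruling line of the beam.

    The constant-intensity surfaces of a Gaussian beam are one-sheet
    hyperboloids ``x^2 + y^2 = r0^2 (1 + ((z - zf)/zR)^2)``, doubly ruled
    surfaces: straight launch lines through the waist circle reproduce the
    Gaussian intensity profile exactly.  ``r0`` is drawn with density
    proportional to ``r0 exp(-2 r0^2 / w0^2)``, the azimuth uniformly, and
    the ruling family by a fair coin.
    """
    u = 1.0 - rng.random()
    r0 = beam.w0 * math.sqrt(-0.5 * math.log(u))
    phi = 2.0 * math.pi * rng.random()
    sigma = 1.0 if rng.random() < 0.5 else -1.0
    cp, sp = math.cos(phi), math.sin(phi)
    norm = math.sqrt(r0 * r0 + beam.zR * beam.zR)
    direction = np.array([
        -sigma * r0 * sp / norm,
        sigma * r0 * cp / norm,
        beam.zR / norm,
    ])
    ratio = beam.zf / beam.zR
    position = np.array([
        r0 * cp + sigma * ratio * r0 * sp,
        r0 * sp - sigma * ratio * r0 * cp,
        0.0,
    ])
    return PhotonState(position=position, direction=direction)


def sample_step(mus: float, rng: np.random.Generator) -> float:
    """Exponential free path ``-ln(xi)/mus`` between scatter events."""
    if mus <= 0.0:
        raise ValueError("sample_step requires mus > 0; a non-scattering "
                         "medium has an infinite free path")
    return -math.log(1.0 - rng.random()) / mus


def sample_hg(g: float, rng: np.random.Generator) -> float:
    """Scattering cosine from the Henyey-Greenstein phase function."""
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy g must be in (-1, 1), got {g!r}")
    return _kernel._hg_cos(g, rng.random())


def rotate_direction(direction: np.ndarray, cos_theta: float,
                     phi: float) -> np.ndarray:
    """Rotate a unit vector by polar angle theta (given as its cosine) and
    azimuth phi about itself; numerically stable near the vertical."""
    vx, vy, vz = (float(direction[0]), float(direction[1]), float(direction[2]))
    ct = float(cos_theta)
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(vz) > 0.99999:
        new = np.array([st * cp, st * sp, ct if vz > 0 else -ct])
    else:
        den = math.sqrt(1.0 - vz * vz)
        new = np.array([
            st * (vx * vz * cp - vy * sp) / den + vx * ct,
            st * (vy * vz * cp + vx * sp) / den + vy * ct,
            -den * st * cp + vz * ct,
        ])
    return new / np.linalg.norm(new)


def attenuate(weight: float, mua: float, s: float) -> float:
    """Continuous absorption weighting over a path of length ``s``."""
    if s < 0:
        raise ValueError("path length must be >= 0")
    return weight * math.exp(-mua * s)


# ---------------------------------------------------------------------------
# reference photon loop
# ---------------------------------------------------------------------------

def run_photon(config: SimulationConfig,
               rng: np.random.Generator) -> Optional[PhotonRecord]:
    """Propagate a single packet; return its exit record or None.

    Readable reference implementation of the batch kernel's inner loop
    (identical physics, independent code path).
    """
    beam, med, det = config.beam, config.medium, config.detection
    state = sample_launch(beam, rng)
    cos_tmax = math.cos(det.theta_max)
    while True:
        if med.mus > 0.0:
            s = sample_step(med.mus, rng)
        else:
            s = 1e30
        vz = state.direction[2]
        z = state.position[2]
        if vz < 0.0 and z + s * vz <= 0.0:
            s_exit = -z / vz
            state.weight = attenuate(state.weight, med.mua, s_exit)
            state.opl += med.n * s_exit
            state.position = state.position + state.direction * s_exit
            cos_ti = -vz
            if state.n_scatters >= 1 and cos_ti > cos_tmax:
                ls = state.last_scatter
                return PhotonRecord(
                    weight=state.weight,
                    exit_x=state.position[0], exit_y=state.position[1],
                    vx=state.direction[0], vy=state.direction[1], vz=vz,
                    theta_i=math.acos(min(1.0, cos_ti)),
                    opl_total=state.opl,
                    lsx=ls[0], lsy=ls[1], lsz=ls[2],
                    n_scatters=state.n_scatters,
                )
            return None
        state.position = state.position + state.direction * s
        state.weight = attenuate(state.weight, med.mua, s)
        state.opl += med.n * s
        if state.weight < det.weight_cutoff:
            return None
        if state.opl > det.max_opl:
            return None
        ct = sample_hg(med.g, rng)
        psi = 2.0 * math.pi * rng.random()
        state.direction = rotate_direction(state.direction, ct, psi)
        state.last_scatter = state.position.copy()
        state.n_scatters += 1


def run_simulation_reference(config: SimulationConfig) -> TransportResult:
    """Plain-Python transport run: one independent stream per photon, so a
    given (seed, photon index) always reproduces the same history.  Slow;
    intended for small-N cross-checks against :func:`run_simulation`."""
    records = []
    counters = Counters()
    for i in range(config.n_photons):
        rng = make_rng_stream(config.seed, i)
        rec = run_photon(config, rng)
        counters.launched += 1
        if rec is not None:
            counters.recorded += 1
            records.append(rec)
    # the reference path does not distinguish loss channels
    counters.discarded_angle = counters.launched - counters.recorded
    return TransportResult(records=PhotonRecords.from_records(records),
                           counters=counters)


# ---------------------------------------------------------------------------
# compiled batch run
# ---------------------------------------------------------------------------

#: photons per kernel chunk in record mode; bounds peak memory at
#: chunk * 12 * 8 bytes for the staging array.
RECORD_CHUNK = 2_000_000


def run_simulation(config: SimulationConfig, seed: int | None = None) -> TransportResult:
    """Run the compiled transport kernel, returning exit records + counters.

    Deterministic given (config, seed).  For photon counts above ~10^7
    prefer the streaming profile accumulation in :mod:`octsim.simulate`,
    which does not materialise records.
    """
    if seed is None:
        seed = config.seed
    beam, med, det = config.beam, config.medium, config.detection
    counters_arr = np.zeros(5, dtype=np.int64)
    chunks = []
    remaining = config.n_photons
    chunk_id = 0
    while remaining > 0:
        n = min(remaining, RECORD_CHUNK)
        out = np.empty((n, len(RECORD_COLUMNS)), dtype=np.float64)
        m = _kernel.run_batch_records(
            n, kernel_seed(seed, chunk_id),
            beam.w0, beam.zR, beam.zf,
            med.mua, med.mus, med.g, med.n,
            math.cos(det.theta_max), det.weight_cutoff, det.max_opl,
            out, counters_arr,
        )
        chunks.append(out[:m].copy())
        remaining -= n
        chunk_id += 1
    arr = np.concatenate(chunks, axis=0) if chunks else np.empty((0, 12))
    counters = Counters(*(int(c) for c in counters_arr))
    return TransportResult(records=PhotonRecords.from_array(arr),
                           counters=counters)
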