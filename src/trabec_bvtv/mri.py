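"""Dual-echo UTE MR forward model.

Each coarse MR voxel with true bone fraction ``f`` produces the noiseless
two-compartment signal

    S(TE) = rho_bone * f * exp(-TE / T2*_bone)
          + rho_marrow * (1 - f) * exp(-TE / T2*_marrow)

Bone bound water (T2* of a few hundred microseconds) is visible at the
ultrashort first echo and has decayed to near zero by the second echo at
2.2 ms; marrow water and fat (long T2*, in phase at 3T at 2.2 ms) persist
at both echoes and are lumped into one compartment with a single effective
proton density. ``rho_marrow > rho_bone`` encodes the higher proton density
per unit volume of fatty marrow, which drives the dual-echo estimator's
systematic underestimation of BVTV.

Noise is Rician by default (magnitude reconstruction); Gaussian is
available for analytic tests. Simulation is purely image-domain: the
downstream analysis consumes reconstructed magnitude images, so k-space
trajectory and coil effects are out of scope, and any steady-state T1/TR
weighting multiplies both echoes equally and cancels in the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantom import downsample_bvtv
from .volumes import DualEchoVolume, MicrostructureGrid, ScalarVolume

__all__ = ["SignalModelParams", "simulate_dual_echo", "two_compartment_signal"]

#: Upper bound on the first echo time for the ultrashort regime, ms.
ULTRASHORT_TE_MAX = 0.1


@dataclass(frozen=True)
class SignalModelParams:
    """Dual-echo UTE acquisition and tissue parameters.

    Parameters
    ----------
    te_pair:
        Echo times in ms; default (0.032, 2.2). The first must be in the
        ultrashort regime (<= 0.1 ms); the second is where fat and water
        are in phase at 3T, so fat-water phase is not otherwise modelled.
    t2star_bone, t2star_marrow:
        Apparent transverse relaxation times in ms. Bone T2* is a few
        hundred microseconds (default 0.35 ms); marrow is long relative to
        the second echo (default 30 ms). ``math.inf`` is accepted for
        no-decay limits.
    rho_bone, rho_marrow:
        Relative proton densities per unit volume. Fatty marrow carries
        more protons per volume than bone water; default ratio 1.3.
    noise_sigma:
        Per-channel noise standard deviation in intensity units (0 = noiseless).
    noise_model:
        ``"rician"`` (magnitude, default) or ``"gaussian"``.
    mr_voxel:
        MR voxel size in mm (default 0.5); must be an integer multiple of
        the microstructure voxel size.
    seed:
        Noise seed.
    """

    te_pair: tuple[float, float] = (0.032, 2.2)
    t2star_bone: float = 0.35
    t2star_marrow: float = 30.0
    rho_bone: float = 1.0
    rho_marrow: float = 1.3
    noise_sigma: float = 0.0
    noise_model: str = "rician"
    mr_voxel: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        te1, te2 = self.te_pair
        if not (0 < te1 < te2):
            raise ValueError("te_pair must be strictly increasing and positive")
        if te1 > ULTRASHORT_TE_MAX:
            raise ValueError(
                f"first echo must be ultrashort (<= {ULTRASHORT_TE_MAX} ms)"
            )
        if not (self.t2star_bone > 0 and self.t2star_marrow > 0):
            raise ValueError("T2* values must be positive")
        if not (self.rho_bone > 0 and self.rho_marrow > 0):
            raise ValueError("proton densities must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError("noise_model must be 'rician' or 'gaussian'")
        if not self.mr_voxel > 0:
            raise ValueError("mr_voxel must be positive")


def two_compartment_signal(
    fraction: np.ndarray | float, te: float, params: SignalModelParams
) -> np.ndarray | float:
    """Noiseless signal of a voxel with bone fraction ``fraction`` at echo ``te``."""
    f = np.asarray(fraction, dtype=float)
    decay_bone = math.exp(-te / params.t2star_bone) if np.isfinite(params.t2star_bone) else 1.0
    decay_marrow = (
        math.exp(-te / params.t2star_marrow) if np.isfinite(params.t2star_marrow) else 1.0
    )
    return params.rho_bone * f * decay_bone + params.rho_marrow * (1.0 - f) * decay_marrow


def _add_noise(signal: np.ndarray, sigma: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal
    if model == "rician":
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        return np.hypot(re, im)
    return np.clip(signal + rng.normal(0.0, sigma, signal.shape), 0.0, None)


def simulate_dual_echo(
    grid: MicrostructureGrid, params: SignalModelParams
) -> DualEchoVolume:
    """Simulate the two UTE echoes of a microstructure specimen.

    Partial-volume mixing is exact block averaging of the fine binary grid
    (linear mixing of proton-density-weighted magnitude signals); the two
    echoes are returned co-registered on the coarse MR grid. Noise, when
    enabled, is drawn independently per voxel per echo from the given seed.
    """
    fraction = downsample_bvtv(grid, params.mr_voxel).intensities
    rng = np.random.default_rng(params.seed)
    echoes = []
    for te in params.te_pair:
        signal = np.asarray(two_compartment_signal(fraction, te, params), dtype=float)
        signal = _add_noise(signal, params.noise_sigma, params.noise_model, rng)
        echoes.append(
            ScalarVolume(
                intensities=signal,
                voxel_size=params.mr_voxel,
                modality="MR_echo",
                meta={
                    "te_ms": te,
                    "noise_sigma": params.noise_sigma,
                    "noise_model": params.noise_model,
                    "specimen_id": grid.specimen_id,
                },
            )
        )
    return DualEchoVolume(echo1=echoes[0], echo2=echoes[1], te_pair=params.te_pair)
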