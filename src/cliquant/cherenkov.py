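"""Cherenkov emission physics and a lightweight positron transport model.

Covers the band-integrated Frank-Tamm photon yield, the kinetic-energy
threshold for Cherenkov emission, sampling of allowed-shape beta spectra,
and a continuous-slowing-down positron track model with Gaussian
(Highland-style) multiple-scattering kicks.  The track model feeds the
spread-function Monte Carlo; it is a deliberately simple stand-in for full
condensed-history electron transport and is validated through the spread
function morphology it produces.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ALPHA_FS",
    "ELECTRON_REST_KEV",
    "BetaSpectrum",
    "EmissionBand",
    "StoppingPowerTable",
    "load_y86_spectrum",
    "load_water_stopping_power",
    "frank_tamm_yield",
    "threshold_kinetic_energy",
    "beta_from_kinetic_energy",
    "allowed_beta_shape",
    "sample_beta_energy",
    "positron_track",
]

ALPHA_FS = 1.0 / 137.035999  # fine-structure constant
ELECTRON_REST_KEV = 511.0
_RADIATION_LENGTH_WATER_CM = 36.08


@dataclass(frozen=True)
class EmissionBand:
    """Wavelength band over which Cherenkov photons are emitted/scored."""

    lambda_min_nm: float = 400.0
    lambda_max_nm: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.lambda_min_nm < self.lambda_max_nm:
            raise ValueError("need 0 < lambda_min < lambda_max")


@dataclass(frozen=True)
class BetaSpectrum:
    """Beta-decay branch table: (endpoint keV, intensity) pairs summing to 1."""

    isotope: str
    endpoints_kev: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.endpoints_kev, float)
        i = np.asarray(self.intensities, float)
        if e.shape != i.shape or e.ndim != 1:
            raise ValueError("branch arrays must be 1-D and equal length")
        if np.any(e <= 0):
            raise ValueError("endpoint energies must be positive")
        if abs(i.sum() - 1.0) > 1e-9:
            raise ValueError(f"branch intensities sum to {i.sum()}, expected 1")
        object.__setattr__(self, "endpoints_kev", e)
        object.__setattr__(self, "intensities", i)

    @classmethod
    def from_json(cls, path) -> "BetaSpectrum":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            isotope=d["isotope"],
            endpoints_kev=np.array([b["endpoint_kev"] for b in d["branches"]]),
            intensities=np.array([b["intensity"] for b in d["branches"]]),
        )


@dataclass(frozen=True)
class StoppingPowerTable:
    """Collision stopping power and CSDA range vs kinetic energy (water)."""

    energy_kev: np.ndarray
    stopping_kev_per_cm: np.ndarray
    csda_range_cm: np.ndarray

    def stopping_power(self, energy_kev):
        return np.interp(energy_kev, self.energy_kev, self.stopping_kev_per_cm)

    def csda_range(self, energy_kev):
        return np.interp(energy_kev, self.energy_kev, self.csda_range_cm)


def load_y86_spectrum() -> BetaSpectrum:
    ref = resources.files("cliquant.data").joinpath("y86_beta_spectrum.json")
    with resources.as_file(ref) as p:
        return BetaSpectrum.from_json(p)


def load_water_stopping_power() -> StoppingPowerTable:
    ref = resources.files("cliquant.data").joinpath("water_stopping_power.csv")
    with resources.as_file(ref) as p:
        d = np.loadtxt(p, delimiter=",", skiprows=1)
    return StoppingPowerTable(d[:, 0], d[:, 1], d[:, 2])


def frank_tamm_yield(beta: float, n: float, band: EmissionBand) -> float:
    """Cherenkov photons emitted per cm of particle path within the band.

    Band integral of the classical Frank-Tamm differential
    d2N/(dx dlambda) = (2 pi alpha / lambda^2) (1 - 1/(beta^2 n^2)),
    i.e. 2 pi alpha (1/lmin - 1/lmax)(1 - 1/(beta^2 n^2)); zero below the
    threshold beta*n <= 1.
    """
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    if n <= 1:
        raise ValueError("refractive index must exceed 1")
    if beta * n <= 1.0:
        return 0.0
    inv_band_cm = (1.0 / band.lambda_min_nm - 1.0 / band.lambda_max_nm) * 1e7
    return 2.0 * np.pi * ALPHA_FS * inv_band_cm * (1.0 - 1.0 / (beta * n) ** 2)


def threshold_kinetic_energy(n: float) -> float:
    """Kinetic energy (keV) at which an electron reaches beta = 1/n."""
    if n <= 1:
        raise ValueError("refractive index must exceed 1")
    return ELECTRON_REST_KEV * (n / np.sqrt(n * n - 1.0) - 1.0)


def beta_from_kinetic_energy(energy_kev):
    gamma = 1.0 + np.asarray(energy_kev, float) / ELECTRON_REST_KEV
    return np.sqrt(1.0 - 1.0 / (gamma * gamma))


def allowed_beta_shape(energy_kev, endpoint_kev):
    """Unnormalized allowed beta spectrum p*W*(W0-W)^2 (Coulomb term omitted)."""
    e = np.asarray(energy_kev, float)
    w = 1.0 + e / ELECTRON_REST_KEV
    w0 = 1.0 + endpoint_kev / ELECTRON_REST_KEV
    p = np.sqrt(np.clip(w * w - 1.0, 0.0, None))
    out = p * w * (w0 - w) ** 2
    return np.where((e > 0) & (e < endpoint_kev), out, 0.0)


def sample_beta_energy(
    spectrum: BetaSpectrum, rng: np.random.Generator, size: int | None = None
):
    """Draw beta kinetic energies (keV): branch by intensity, energy by
    rejection against the allowed shape."""
    n = 1 if size is None else int(size)
    branches = rng.choice(len(spectrum.endpoints_kev), size=n, p=spectrum.intensities)
    out = np.empty(n)
    for i, b in enumerate(branches):
        e0 = spectrum.endpoints_kev[b]
        grid = np.linspace(0, e0, 256)
        fmax = allowed_beta_shape(grid, e0).max() * 1.05
        while True:
            e = rng.random() * e0
            if rng.random() * fmax <= allowed_beta_shape(e, e0):
                out[i] = e
                break
    return float(out[0]) if size is None else out


def positron_track(
    energy_kev: float,
    rng: np.random.Generator,
    stopping: StoppingPowerTable | None = None,
    step_cm: float = 0.01,
    scattering: bool = True,
    min_energy_kev: float = 10.0,
    max_steps: int = 100_000,
):
    """Continuous-slowing-down positron track with multiple-scattering kicks.

    Returns (positions, directions, lengths, betas): per-segment start
    position (cm, origin at emission), unit direction, segment length and
    particle beta over the segment.  The direction receives a Gaussian
    angular kick of Highland width each step; energy decrements via the
    water collision stopping power until ``min_energy_kev``.
    """
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    if stopping is None:
        stopping = load_water_stopping_power()

    pos = np.zeros(3)
    # isotropic initial direction
    cos_t = 2.0 * rng.random() - 1.0
    phi = 2.0 * np.pi * rng.random()
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    d = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])

    positions, directions, lengths, betas = [], [], [], []
    e = float(energy_kev)
    for _ in range(max_steps):
        if e <= min_energy_kev:
            break
        beta = beta_from_kinetic_energy(e)
        s0 = stopping.stopping_power(e)
        if s0 <= 0:
            raise RuntimeError("non-positive stopping power: infinite range guard")
        ds = min(step_cm, max(e - min_energy_kev, 0.0) / s0)
        # midpoint stopping power: second-order in the step so the total path
        # length tracks the CSDA range closely at all start energies
        s = stopping.stopping_power(max(e - 0.5 * s0 * ds, min_energy_kev))
        ds = min(step_cm, max(e - min_energy_kev, 0.0) / s)
        positions.append(pos.copy())
        directions.append(d.copy())
        lengths.append(ds)
        betas.append(float(beta))
        pos = pos + d * ds
        e -= s * ds
        if scattering:
            p_kev = np.sqrt(e * (e + 2 * ELECTRON_REST_KEV)) if e > 0 else 1.0
            theta0 = (13600.0 / (max(beta, 1e-6) * max(p_kev, 1.0))) * np.sqrt(
                ds / _RADIATION_LENGTH_WATER_CM
            )
            d = _kick_direction(d, theta0, rng)
    else:
        raise RuntimeError("track exceeded max_steps: infinite range guard")

    return (
        np.array(positions).reshape(-1, 3),
        np.array(directions).reshape(-1, 3),
        np.array(lengths),
        np.array(betas),
    )


def _kick_direction(d: np.ndarray, theta0: float, rng: np.random.Generator) -> np.ndarray:
    """Apply independent Gaussian angular kicks in two orthogonal planes."""
    tx, ty = rng.normal(0.0, theta0, size=2)
    # local orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[2]) > 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    nd = d + tx * u + ty * v
    return nd / np.linalg.norm(nd)
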