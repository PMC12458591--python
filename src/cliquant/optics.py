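"""Wavelength-resolved tissue optical properties.

Absorption is composed from the principal skin chromophores (oxy/deoxy
blood, water, fat) following the standard Jacques parameterization; reduced
scattering is split into a Rayleigh component (``~ lambda^-4``) and a Mie
component (``~ lambda^-b``), both anchored at 500 nm by the total reduced
scattering coefficient ``a'``.  Scattering anisotropy uses the
Henyey-Greenstein phase function; Mie events mix a forward and a backward
lobe (double Henyey-Greenstein).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ChromophoreSpectrum",
    "TissueComposition",
    "OpticalCoefficients",
    "load_bundled_spectra",
    "default_skin_composition",
    "absorption_coefficient",
    "rayleigh_scattering",
    "mie_scattering",
    "effective_attenuation",
    "beer_lambert_intensity",
    "sample_scatter_cosine",
    "sample_hg_cosine",
    "optical_coefficient_table",
]


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Absorption spectrum of a pure chromophore on a strictly increasing nm grid."""

    name: str
    wavelengths_nm: np.ndarray
    mu_a_per_cm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, float)
        m = np.asarray(self.mu_a_per_cm, float)
        if w.ndim != 1 or w.shape != m.shape:
            raise ValueError(f"{self.name}: grid and values must be 1-D and equal length")
        if not np.all(np.diff(w) > 0):
            raise ValueError(f"{self.name}: wavelength grid must be strictly increasing")
        if np.any(m < 0):
            raise ValueError(f"{self.name}: absorption values must be non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "mu_a_per_cm", m)

    def mu_a(self, wavelength_nm: float) -> float:
        """Linear interpolation; querying outside the tabulated grid is an error."""
        w = np.asarray(wavelength_nm, float)
        if np.any(w < self.wavelengths_nm[0]) or np.any(w > self.wavelengths_nm[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside the grid of spectrum "
                f"'{self.name}' [{self.wavelengths_nm[0]}, {self.wavelengths_nm[-1]}]"
            )
        return np.interp(w, self.wavelengths_nm, self.mu_a_per_cm)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "ChromophoreSpectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(name or str(path), data[:, 0], data[:, 1])


@dataclass(frozen=True)
class TissueComposition:
    """Chromophore fractions and scattering parameters of a tissue.

    Fractions are dimensionless in [0, 1]; ``a_prime`` is the total reduced
    scattering coefficient at 500 nm in 1/cm.  ``g_f``/``g_b`` are the
    forward/backward Henyey-Greenstein anisotropies of the Mie lobe and
    ``mie_fb`` the probability of the forward lobe.
    """

    B: float  # blood volume fraction
    S: float  # hemoglobin oxygen saturation
    W: float  # water fraction
    F: float  # fat fraction
    a_prime: float  # reduced scattering at 500 nm, 1/cm
    f_ray: float  # Rayleigh-scattered fraction at 500 nm
    b_mie: float  # Mie scattering power
    g_f: float = 0.91
    g_b: float = 0.87
    mie_fb: float = 0.85
    n: float = 1.4  # refractive index

    def __post_init__(self) -> None:
        for nm in ("B", "S", "W", "F", "f_ray", "mie_fb"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} must lie in [0, 1]")
        if self.a_prime <= 0:
            raise ValueError("a_prime must be positive")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        for nm in ("g_f", "g_b"):
            if not -1.0 < getattr(self, nm) < 1.0:
                raise ValueError(f"{nm} must lie in (-1, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "TissueComposition":
        """Build from a mapping using the field symbols of the literature
        parameterization (``B, S, W, F, a', fRay, bmie, gF, gB, MieFB, n``).

        ``S``, ``W``, ``F`` given as percentages (>1) are divided by 100;
        ``B`` is read as *percent* blood volume when ``percent_blood`` is set
        in the mapping (default true), the only self-consistent reading of
        the published skin values.
        """
        alias = {"a'": "a_prime", "aprime": "a_prime", "fRay": "f_ray",
                 "bmie": "b_mie", "bMie": "b_mie", "gF": "g_f", "gB": "g_b",
                 "MieFB": "mie_fb"}
        percent_blood = bool(d.pop("percent_blood", True)) if isinstance(d, dict) else True
        kw = {}
        for k, v in d.items():
            kw[alias.get(k, k)] = v
        for nm in ("S", "W", "F"):
            if nm in kw and kw[nm] > 1.0:
                kw[nm] = kw[nm] / 100.0
        if percent_blood and "B" in kw:
            kw["B"] = kw["B"] / 100.0
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "TissueComposition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_json(cls, path) -> "TissueComposition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class OpticalCoefficients:
    wavelength_nm: float
    mu_a: float
    mu_s_ray: float
    mu_s_mie: float
    mu_eff: float = field(default=0.0)

    @property
    def mu_s_prime(self) -> float:
        return self.mu_s_ray + self.mu_s_mie


_BUNDLED = {
    "oxy": "mu_a_blood_oxy.csv",
    "deoxy": "mu_a_blood_deoxy.csv",
    "water": "mu_a_water.csv",
    "fat": "mu_a_fat.csv",
}


def load_bundled_spectra() -> dict[str, ChromophoreSpectrum]:
    """Load the packaged chromophore absorption tables (400-1000 nm)."""
    out = {}
    for name, fname in _BUNDLED.items():
        ref = resources.files("cliquant.data").joinpath(fname)
        with resources.as_file(ref) as p:
            out[name] = ChromophoreSpectrum.from_csv(p, name=name)
    return out


def default_skin_composition() -> TissueComposition:
    """Published murine skin parameterization used throughout the package."""
    return TissueComposition.from_dict(
        {"B": 0.34, "S": 98.5, "W": 21.4, "F": 27.7, "a'": 48.0,
         "fRay": 0.409, "bmie": 0.702, "gF": 0.91, "gB": 0.87,
         "MieFB": 0.85, "n": 1.4}
    )


def absorption_coefficient(
    comp: TissueComposition,
    spectra: dict[str, ChromophoreSpectrum],
    wavelength_nm,
) -> float:
    """Composite tissue absorption coefficient in 1/cm.

    mu_a = B*S*mu_oxy + B*(1-S)*mu_deoxy + W*mu_water + F*mu_fat; the minor
    skin chromophores (bilirubin, beta-carotene, melanin) are negligible in
    nude-mouse skin and omitted.
    """
    return (
        comp.B * comp.S * spectra["oxy"].mu_a(wavelength_nm)
        + comp.B * (1.0 - comp.S) * spectra["deoxy"].mu_a(wavelength_nm)
        + comp.W * spectra["water"].mu_a(wavelength_nm)
        + comp.F * spectra["fat"].mu_a(wavelength_nm)
    )


def rayleigh_scattering(comp: TissueComposition, wavelength_nm) -> float:
    """Reduced Rayleigh scattering coefficient, a'*fRay*(lambda/500)^-4, 1/cm."""
    lam = np.asarray(wavelength_nm, float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    return comp.a_prime * comp.f_ray * (lam / 500.0) ** -4


def mie_scattering(comp: TissueComposition, wavelength_nm) -> float:
    """Reduced Mie scattering coefficient, a'*(1-fRay)*(lambda/500)^-b, 1/cm."""
    lam = np.asarray(wavelength_nm, float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    return comp.a_prime * (1.0 - comp.f_ray) * (lam / 500.0) ** -comp.b_mie


def effective_attenuation(mu_a, mu_s_prime) -> float:
    """Diffusion-theory effective attenuation sqrt(3*mu_a*(mu_s' + mu_a)), 1/cm."""
    mu_a = np.asarray(mu_a, float)
    mu_s_prime = np.asarray(mu_s_prime, float)
    if np.any(mu_a < 0) or np.any(mu_s_prime < 0):
        raise ValueError("coefficients must be non-negative")
    return np.sqrt(3.0 * mu_a * (mu_s_prime + mu_a))


def beer_lambert_intensity(i0, mu_eff, depth_cm) -> float:
    """Single-exponential attenuation baseline I0*exp(-mu_eff*d).

    Diagnostic only: the calibration pipeline measures the depth dependence
    empirically instead of assuming this monochromatic model.
    """
    return i0 * np.exp(-np.asarray(mu_eff, float) * np.asarray(depth_cm, float))


def coefficients_at(
    comp: TissueComposition,
    spectra: dict[str, ChromophoreSpectrum],
    wavelength_nm: float,
) -> OpticalCoefficients:
    mu_a = absorption_coefficient(comp, spectra, wavelength_nm)
    mu_r = rayleigh_scattering(comp, wavelength_nm)
    mu_m = mie_scattering(comp, wavelength_nm)
    return OpticalCoefficients(
        wavelength_nm=float(wavelength_nm), mu_a=float(mu_a),
        mu_s_ray=float(mu_r), mu_s_mie=float(mu_m),
        mu_eff=float(effective_attenuation(mu_a, mu_r + mu_m)),
    )


def optical_coefficient_table(
    comp: TissueComposition,
    spectra: dict[str, ChromophoreSpectrum] | None = None,
    lambda_min_nm: float = 400.0,
    lambda_max_nm: float = 1000.0,
    step_nm: float = 2.0,
):
    """Vectorized (wavelength, mu_a, mu_s_ray, mu_s_mie) arrays for the Monte Carlo."""
    if spectra is None:
        spectra = load_bundled_spectra()
    lam = np.arange(lambda_min_nm, lambda_max_nm + 0.5 * step_nm, step_nm)
    mu_a = np.array([absorption_coefficient(comp, spectra, x) for x in lam])
    return lam, mu_a, rayleigh_scattering(comp, lam), mie_scattering(comp, lam)


def sample_hg_cosine(g: float, rng: np.random.Generator, size=None):
    """Inverse-CDF sample of the Henyey-Greenstein scattering cosine."""
    u = rng.random(size)
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - t * t) / (2.0 * g)


def sample_scatter_cosine(
    comp: TissueComposition,
    event_kind: str,
    rng: np.random.Generator,
    size=None,
):
    """Scattering cosine for one event type.

    Rayleigh events are isotropic; Mie events draw from the double
    Henyey-Greenstein: with probability ``mie_fb`` the forward lobe ``g_f``,
    otherwise a backward-peaked lobe with parameter ``-g_b``.
    """
    if event_kind == "rayleigh":
        return 2.0 * rng.random(size) - 1.0
    if event_kind == "mie":
        u = rng.random(size)
        fwd = u < comp.mie_fb
        cos_f = sample_hg_cosine(comp.g_f, rng, size)
        cos_b = sample_hg_cosine(-comp.g_b, rng, size)
        return np.where(fwd, cos_f, cos_b) if size is not None else (
            cos_f if fwd else cos_b
        )
    raise ValueError(f"unknown scatter event kind: {event_kind!r}")
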