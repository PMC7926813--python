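"""Dielectric models for tissues and mixture components.

All spectra follow the electrical-engineering sign convention

    eps = eps' - j*eps'',   eps'' >= 0,   time factor e^{+j*omega*t},

so the complex values stored in a :class:`DielectricSpectrum` have a
non-positive imaginary part.  The loss factor ``eps''`` is exposed as a
non-negative array, and the effective conductivity is

    sigma_eff = 2*pi*f * eps0 * eps''   [S/m].

Three model families are provided:

* :class:`ColeColeModel` — multi-pole Cole–Cole dispersion, the standard
  parametric description of biological tissues.
* :class:`DebyeModel` — single-pole relaxation, used for Triton X-100.
* :class:`SalineModel` — Debye model of aqueous NaCl whose static
  permittivity, relaxation time and ionic conductivity are parametric in
  salinity and temperature (Stogryn-form polynomials), together with the
  analytic salinity derivative needed by the recipe optimizer.

Tissue parameter sets (10 head/reference tissues) and the TX-100 Debye
fit are vendored as JSON fixtures under ``tmmkit/data``; each fixture
records its provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

# NaCl molar mass, g/mol: converts the user-facing g/L concentration to
# normality (mol/L) for the saline polynomials.
NACL_MOLAR_MASS = 58.44

#: validity window of the saline parametric model
SALINE_TEMP_WINDOW_C = (0.0, 50.0)
SALINE_NACL_WINDOW_G_PER_L = (0.0, 120.0)


class ValidationError(ValueError):
    """Raised when a model parameter violates its physical constraints."""


# ---------------------------------------------------------------------------
# frequency grid and spectrum containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyGrid:
    """Sampling grid in hertz, linear or logarithmic.

    The default grid used throughout the package is 26 linearly spaced
    points over the 0.5–3 GHz design band.
    """

    f_min: float = 0.5e9
    f_max: float = 3.0e9
    n_points: int = 26
    spacing: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 < self.f_min < self.f_max:
            raise ValidationError(
                f"require 0 < f_min < f_max, got f_min={self.f_min}, f_max={self.f_max}"
            )
        if self.n_points < 2:
            raise ValidationError(f"n_points must be >= 2, got {self.n_points}")
        if self.spacing not in ("linear", "log"):
            raise ValidationError(f"spacing must be 'linear' or 'log', got {self.spacing!r}")

    @property
    def frequencies(self) -> np.ndarray:
        if self.spacing == "linear":
            return np.linspace(self.f_min, self.f_max, self.n_points)
        return np.geomspace(self.f_min, self.f_max, self.n_points)

    @classmethod
    def single(cls, f: float) -> "FrequencyGrid":
        """Degenerate two-point grid used to evaluate at (almost) one frequency."""
        return cls(f_min=f, f_max=f * (1 + 1e-12), n_points=2)


@dataclass(frozen=True)
class DielectricSpectrum:
    """Complex relative permittivity sampled on a frequency grid.

    ``eps`` holds eps' - j*eps'' (imaginary part <= 0).  Use
    :attr:`eps_real`, :attr:`eps_imag` and :attr:`sigma_eff` for the
    conventional positive-loss views.
    """

    frequencies: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        e = np.asarray(self.eps, dtype=complex)
        if f.ndim != 1 or f.shape != e.shape:
            raise ValidationError("frequencies and eps must be 1-D arrays of equal length")
        if np.any(np.diff(f) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        if np.any(e.real < 1.0 - 1e-9):
            raise ValidationError("eps_real must be >= 1 at every frequency")
        if np.any(e.imag > 1e-9):
            raise ValidationError("eps_imag (loss) must be >= 0 at every frequency")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "eps", e)

    @property
    def eps_real(self) -> np.ndarray:
        return self.eps.real

    @property
    def eps_imag(self) -> np.ndarray:
        """Loss factor eps'' >= 0."""
        return -self.eps.imag

    @property
    def sigma_eff(self) -> np.ndarray:
        """Effective conductivity 2*pi*f*eps0*eps'' in S/m."""
        return 2.0 * np.pi * self.frequencies * EPS0 * self.eps_imag

    def at(self, f: float) -> complex:
        """Linearly interpolated complex permittivity at frequency ``f``."""
        re = np.interp(f, self.frequencies, self.eps.real)
        im = np.interp(f, self.frequencies, self.eps.imag)
        return complex(re, im)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_Hz": self.frequencies,
                "eps_real": self.eps_real,
                "eps_imag": self.eps_imag,
                "sigma_S_per_m": self.sigma_eff,
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def write_spectrum_csv(spectrum: DielectricSpectrum, path: Union[str, Path]) -> None:
    """Write a spectrum as CSV (frequency_Hz, eps_real, eps_imag, sigma_S_per_m)."""
    spectrum.to_csv(path)


# ---------------------------------------------------------------------------
# Cole–Cole and Debye models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColeColeModel:
    """Multi-pole Cole–Cole dispersion.

    eps(w) = eps_inf + sum_n delta_eps_n / (1 + (j*w*tau_n)^(1-alpha_n))
             + sigma_static / (j*w*eps0)
    """

    eps_inf: float
    poles: tuple  # of (delta_eps, tau_s, alpha)
    sigma_static: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValidationError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.sigma_static < 0.0:
            raise ValidationError(f"sigma_static must be >= 0, got {self.sigma_static}")
        poles = tuple((float(d), float(t), float(a)) for d, t, a in self.poles)
        for d, t, a in poles:
            if d < 0.0:
                raise ValidationError(f"delta_eps must be >= 0, got {d}")
            if t <= 0.0:
                raise ValidationError(f"tau must be > 0, got {t}")
            if not 0.0 <= a < 1.0:
                raise ValidationError(f"alpha must be in [0, 1), got {a}")
        object.__setattr__(self, "poles", poles)

    def eval(self, frequencies: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * np.asarray(frequencies, dtype=float)
        eps = np.full_like(w, self.eps_inf, dtype=complex)
        for delta, tau, alpha in self.poles:
            eps += delta / (1.0 + (1j * w * tau) ** (1.0 - alpha))
        eps += self.sigma_static / (1j * w * EPS0)
        return eps

    def evaluate(self, grid: FrequencyGrid) -> DielectricSpectrum:
        return DielectricSpectrum(grid.frequencies, self.eval(grid.frequencies))


def eval_cole_cole(model: ColeColeModel, grid: FrequencyGrid) -> DielectricSpectrum:
    """Evaluate a Cole–Cole model on a frequency grid."""
    return model.evaluate(grid)


@dataclass(frozen=True)
class DebyeModel:
    """Single-pole Debye relaxation with an optional static-conductivity term."""

    eps_static: float
    eps_inf: float
    tau: float
    sigma_static: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.eps_static >= self.eps_inf >= 1.0:
            raise ValidationError(
                f"require eps_static >= eps_inf >= 1, got "
                f"eps_static={self.eps_static}, eps_inf={self.eps_inf}"
            )
        if self.tau <= 0.0:
            raise ValidationError(f"tau must be > 0, got {self.tau}")
        if self.sigma_static < 0.0:
            raise ValidationError(f"sigma_static must be >= 0, got {self.sigma_static}")

    def eval(self, frequencies: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * np.asarray(frequencies, dtype=float)
        eps = self.eps_inf + (self.eps_static - self.eps_inf) / (1.0 + 1j * w * self.tau)
        eps = eps + self.sigma_static / (1j * w * EPS0)
        return eps

    def evaluate(self, grid: FrequencyGrid) -> DielectricSpectrum:
        return DielectricSpectrum(grid.frequencies, self.eval(grid.frequencies))


def eval_debye(model: DebyeModel, grid: FrequencyGrid) -> DielectricSpectrum:
    """Evaluate a Debye model on a frequency grid."""
    return model.evaluate(grid)


# ---------------------------------------------------------------------------
# parametric saline (aqueous NaCl) model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SalineModel:
    """Aqueous NaCl permittivity, parametric in salinity and temperature.

    Debye form eps = eps_inf + (eps_s - eps_inf)/(1 + j*w*tau) - j*sigma/(w*eps0)
    with eps_s(T, N), tau(T, N) and the ionic conductivity sigma(T, N) given
    by Stogryn-form polynomial fits in the NaCl normality
    N = nacl_concentration / 58.44 and the Celsius temperature.

    Parameters
    ----------
    nacl_concentration : float
        NaCl concentration in g/L (grams of salt per litre of solution).
    temperature : float
        Temperature in degrees Celsius; validity window 0–50 °C.
    """

    nacl_concentration: float = 0.0
    temperature: float = 25.0

    EPS_INF = 4.9

    def __post_init__(self) -> None:
        lo, hi = SALINE_NACL_WINDOW_G_PER_L
        if not lo <= self.nacl_concentration <= hi:
            raise ValidationError(
                f"nacl_concentration {self.nacl_concentration} g/L outside the "
                f"model's validity window [{lo}, {hi}] g/L"
            )
        tlo, thi = SALINE_TEMP_WINDOW_C
        if not tlo <= self.temperature <= thi:
            raise ValidationError(
                f"temperature {self.temperature} C outside the model's "
                f"validity window [{tlo}, {thi}] C"
            )

    # --- polynomial building blocks (N = normality, T = Celsius) ---

    @property
    def normality(self) -> float:
        return self.nacl_concentration / NACL_MOLAR_MASS

    @staticmethod
    def _eps_static_water(T: float) -> float:
        return 87.74 - 0.40008 * T + 9.398e-4 * T**2 + 1.410e-6 * T**3

    @staticmethod
    def _a(N: float) -> float:
        return 1.0 - 0.2551 * N + 5.151e-2 * N**2 - 6.889e-3 * N**3

    @staticmethod
    def _da_dN(N: float) -> float:
        return -0.2551 + 2 * 5.151e-2 * N - 3 * 6.889e-3 * N**2

    @staticmethod
    def _tau_water(T: float) -> float:
        two_pi_tau = (
            1.1109e-10 - 3.824e-12 * T + 6.938e-14 * T**2 - 5.096e-16 * T**3
        )
        return two_pi_tau / (2.0 * np.pi)

    @staticmethod
    def _b(N: float, T: float) -> float:
        return 0.1463e-2 * N * T + 1.0 - 0.04896 * N - 0.02967 * N**2 + 5.644e-3 * N**3

    @staticmethod
    def _db_dN(N: float, T: float) -> float:
        return 0.1463e-2 * T - 0.04896 - 2 * 0.02967 * N + 3 * 5.644e-3 * N**2

    @staticmethod
    def _sigma25(N: float) -> float:
        return N * (
            10.394 - 2.3776 * N + 0.68258 * N**2 - 0.13538 * N**3 + 1.0086e-2 * N**4
        )

    @staticmethod
    def _dsigma25_dN(N: float) -> float:
        return (
            10.394
            - 2 * 2.3776 * N
            + 3 * 0.68258 * N**2
            - 4 * 0.13538 * N**3
            + 5 * 1.0086e-2 * N**4
        )

    @staticmethod
    def _temp_factor(N: float, T: float) -> float:
        d = 25.0 - T
        return 1.0 - 1.962e-2 * d + 8.08e-5 * d**2 - N * d * (
            3.020e-5 + 3.922e-5 * d + N * (1.721e-5 - 6.584e-6 * d)
        )

    @staticmethod
    def _dtemp_factor_dN(N: float, T: float) -> float:
        d = 25.0 - T
        return -d * (3.020e-5 + 3.922e-5 * d) - 2 * N * d * (1.721e-5 - 6.584e-6 * d)

    # --- assembled quantities ---

    @property
    def eps_static(self) -> float:
        return self._eps_static_water(self.temperature) * self._a(self.normality)

    @property
    def tau(self) -> float:
        return self._tau_water(self.temperature) * self._b(self.normality, self.temperature)

    @property
    def sigma_ionic(self) -> float:
        N, T = self.normality, self.temperature
        return self._sigma25(N) * self._temp_factor(N, T)

    def eval(self, frequencies: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * np.asarray(frequencies, dtype=float)
        eps = self.EPS_INF + (self.eps_static - self.EPS_INF) / (1.0 + 1j * w * self.tau)
        eps = eps + self.sigma_ionic / (1j * w * EPS0)
        return eps

    def evaluate(self, grid: FrequencyGrid) -> DielectricSpectrum:
        return DielectricSpectrum(grid.frequencies, self.eval(grid.frequencies))

    def eval_salinity_derivative(self, frequencies: np.ndarray) -> np.ndarray:
        """Analytic d(eps)/dS at each frequency, S in g/L.

        Chains through the static permittivity, relaxation time and ionic
        conductivity; agrees with a central finite difference of
        :meth:`eval` to better than 1e-6 relative (contract tested).
        """
        N, T = self.normality, self.temperature
        w = 2.0 * np.pi * np.asarray(frequencies, dtype=float)

        eps_s = self.eps_static
        tau = self.tau
        deps_s = self._eps_static_water(T) * self._da_dN(N)
        dtau = self._tau_water(T) * self._db_dN(N, T)
        dsigma = self._dsigma25_dN(N) * self._temp_factor(N, T) + self._sigma25(
            N
        ) * self._dtemp_factor_dN(N, T)

        denom = 1.0 + 1j * w * tau
        d_dN = (
            deps_s / denom
            - (eps_s - self.EPS_INF) * (1j * w * dtau) / denom**2
            + dsigma / (1j * w * EPS0)
        )
        return d_dN / NACL_MOLAR_MASS


def eval_saline(model: SalineModel, grid: FrequencyGrid) -> DielectricSpectrum:
    """Evaluate the parametric saline model on a frequency grid."""
    return model.evaluate(grid)


def saline_salinity_derivative(model: SalineModel, grid: FrequencyGrid) -> np.ndarray:
    """d(eps_saline)/dS per frequency (complex array), S in g/L."""
    return model.eval_salinity_derivative(grid.frequencies)


# ---------------------------------------------------------------------------
# tissue blends and the fixture library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueBlend:
    """Volume-weighted blend of Cole–Cole tissue models.

    The blended complex permittivity is the per-frequency weighted average
    of the component permittivities; weights must be non-negative and sum
    to one.  Used for the reference brain target (75% white matter / 25%
    grey matter).
    """

    models: tuple
    weights: tuple
    name: str = ""

    def __post_init__(self) -> None:
        models = tuple(self.models)
        weights = tuple(float(w) for w in self.weights)
        if len(models) != len(weights) or not models:
            raise ValidationError("need equally many models and weights (at least one)")
        if any(w < 0 for w in weights):
            raise ValidationError("blend weights must be >= 0")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError(f"blend weights must sum to 1, got {sum(weights)!r}")
        object.__setattr__(self, "models", models)
        object.__setattr__(self, "weights", weights)

    def eval(self, frequencies: np.ndarray) -> np.ndarray:
        out = np.zeros(np.shape(frequencies), dtype=complex)
        for model, w in zip(self.models, self.weights):
            out += w * model.eval(frequencies)
        return out

    def evaluate(self, grid: FrequencyGrid) -> DielectricSpectrum:
        return DielectricSpectrum(grid.frequencies, self.eval(grid.frequencies))


#: any object with .eval(frequencies) / .evaluate(grid)
TissueModel = Union[ColeColeModel, DebyeModel, SalineModel, TissueBlend]


def blend_tissues(models: Sequence[ColeColeModel], weights: Sequence[float],
                  name: str = "") -> TissueBlend:
    """Build a volume-weighted blend of tissue models."""
    return TissueBlend(tuple(models), tuple(weights), name=name)


def _data_text(filename: str) -> str:
    return resources.files("tmmkit.data").joinpath(filename).read_text()


def list_tissues() -> list:
    """Names of the vendored tissue fixtures."""
    names = []
    for entry in resources.files("tmmkit.data").iterdir():
        if entry.name.endswith(".json") and entry.name != "triton_x100.json":
            names.append(entry.name[: -len(".json")])
    return sorted(names)


def load_tissue(name: str) -> TissueModel:
    """Load a vendored tissue model (Cole–Cole or blend) by name."""
    try:
        doc = json.loads(_data_text(f"{name}.json"))
    except FileNotFoundError:
        raise KeyError(
            f"unknown tissue {name!r}; available: {', '.join(list_tissues())}"
        ) from None
    return _model_from_doc(doc)


def _model_from_doc(doc: dict) -> TissueModel:
    kind = doc["kind"]
    if kind == "cole_cole":
        return ColeColeModel(
            eps_inf=doc["eps_inf"],
            poles=tuple(tuple(p) for p in doc["poles"]),
            sigma_static=doc["sigma_static"],
            name=doc.get("name", ""),
        )
    if kind == "debye":
        return DebyeModel(
            eps_static=doc["eps_static"],
            eps_inf=doc["eps_inf"],
            tau=doc["tau"],
            sigma_static=doc.get("sigma_static", 0.0),
            name=doc.get("name", ""),
        )
    if kind == "blend":
        components = [load_tissue(c) for c in doc["components"]]
        return TissueBlend(tuple(components), tuple(doc["weights"]),
                           name=doc.get("name", ""))
    raise ValidationError(f"unknown fixture kind {kind!r}")


def load_tx100() -> DebyeModel:
    """The vendored Triton X-100 Debye model."""
    return _model_from_doc(json.loads(_data_text("triton_x100.json")))


def tx100_density_g_per_mL() -> float:
    """TX-100 mass density fixture (g/mL at 25 °C)."""
    return float(json.loads(_data_text("triton_x100.json"))["density_g_per_mL"])
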