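"""Binary mixing laws for the TX-100/saline liquid and their derivatives.

The mixture permittivity ``eps_m`` is computed from the component
permittivities ``eps1`` (Triton X-100) and ``eps2`` (saline) and the
saline volume fraction ``v2`` (``v1 = 1 - v2``).  Five laws are
implemented:

* ``kraszewski`` — square-root-linear:  sqrt(eps_m) = sqrt(eps1) + v2*(sqrt(eps2) - sqrt(eps1))
* ``bottcher``   — implicit effective-medium form
                   (eps_m - eps1)(eps2 + 2 eps_m) = 3 v2 eps_m (eps2 - eps1)
* ``bruggeman``  — symmetric effective-medium form
                   v1 (eps1 - eps_m)/(eps1 + 2 eps_m) + v2 (eps2 - eps_m)/(eps2 + 2 eps_m) = 0
* ``lichtenecker`` — logarithmic rule:  ln eps_m = v1 ln eps1 + v2 ln eps2
* ``looyenga``   — 1/3-power rule:  eps_m^(1/3) = v1 eps1^(1/3) + v2 eps2^(1/3)

Only Kraszewski and Böttcher reproduce measured TX-100/saline mixtures
well over 0.5–3 GHz; the other three are provided for comparison.

All complex roots, logs and fractional powers use the principal branch.
Component permittivities of interest lie in the right half-plane
(eps' > 0, loss >= 0), where the principal branch is unambiguous; the
implicit quadratic laws select the root that is continuous with
``eps_m -> eps1`` as ``v2 -> 0`` and raise :class:`MixingLawError` if no
passive root exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

import numpy as np

from .tissue_dielectrics import (
    DebyeModel,
    DielectricSpectrum,
    FrequencyGrid,
    SalineModel,
    ValidationError,
    load_tx100,
)


class MixingLawError(ValueError):
    """Raised when a mixing law has no admissible (passive) solution."""


class MixingLaw(str, Enum):
    KRASZEWSKI = "kraszewski"
    BOTTCHER = "bottcher"
    LICHTENECKER = "lichtenecker"
    LOOYENGA = "looyenga"
    BRUGGEMAN = "bruggeman"


@dataclass(frozen=True)
class MixtureComposition:
    """The optimization unknown x = (V2, Sm).

    ``v2_saline`` is the saline volume fraction in [0, 1]; ``nacl`` the
    NaCl concentration of the saline phase in g/L.  The TX-100 volume
    fraction is ``v1_tx = 1 - v2_saline``.
    """

    v2_saline: float
    nacl: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.v2_saline <= 1.0:
            raise ValidationError(f"v2_saline must be in [0, 1], got {self.v2_saline}")
        if self.nacl < 0.0:
            raise ValidationError(f"nacl must be >= 0 g/L, got {self.nacl}")

    @property
    def v1_tx(self) -> float:
        return 1.0 - self.v2_saline

    @property
    def tx_vol_percent(self) -> float:
        return 100.0 * self.v1_tx

    def as_array(self) -> np.ndarray:
        return np.array([self.v2_saline, self.nacl], dtype=float)


# ---------------------------------------------------------------------------
# the laws
# ---------------------------------------------------------------------------

def _quadratic_mixture_root(a, b, c, eps1, v2):
    """Root of a*eps^2 + b*eps + c = 0 continuous with eps->eps1 at v2->0.

    For passive components the physical root lies in the right half-plane
    while the spurious one (-eps2/2 at v2=0) lies in the left; select by
    real part and enforce passivity.
    """
    disc = np.sqrt(b * b - 4.0 * a * c)
    r1 = (-b + disc) / (2.0 * a)
    r2 = (-b - disc) / (2.0 * a)
    eps_m = np.where(r1.real >= r2.real, r1, r2)
    if np.any(eps_m.real <= 0.0) or np.any(eps_m.imag > 1e-9):
        raise MixingLawError(
            f"no admissible passive root (eps1={eps1!r}, v2={v2!r})"
        )
    return eps_m


def mix(law: MixingLaw, eps1, eps2, v2: float):
    """Complex mixture permittivity eps_m under the named law.

    ``eps1``/``eps2`` may be complex scalars or arrays (eps' - j eps''
    convention); ``v2`` is the saline volume fraction.
    """
    law = MixingLaw(law)
    if not 0.0 <= v2 <= 1.0:
        raise ValidationError(f"v2 must be in [0, 1], got {v2}")
    eps1 = np.asarray(eps1, dtype=complex)
    eps2 = np.asarray(eps2, dtype=complex)
    v1 = 1.0 - v2

    if law is MixingLaw.KRASZEWSKI:
        s = np.sqrt(eps1) + v2 * (np.sqrt(eps2) - np.sqrt(eps1))
        return s * s
    if law is MixingLaw.LICHTENECKER:
        return np.exp(v1 * np.log(eps1) + v2 * np.log(eps2))
    if law is MixingLaw.LOOYENGA:
        c = v1 * eps1 ** (1.0 / 3.0) + v2 * eps2 ** (1.0 / 3.0)
        return c ** 3
    if law is MixingLaw.BOTTCHER:
        # (eps_m - eps1)(eps2 + 2 eps_m) = 3 v2 eps_m (eps2 - eps1)
        a = 2.0 * np.ones_like(eps1)
        b = eps2 - 2.0 * eps1 - 3.0 * v2 * (eps2 - eps1)
        c = -eps1 * eps2
        return _quadratic_mixture_root(a, b, c, eps1, v2)
    # Bruggeman symmetric:
    # v1 (eps1 - eps_m)(eps2 + 2 eps_m) + v2 (eps2 - eps_m)(eps1 + 2 eps_m) = 0
    a = -2.0 * np.ones_like(eps1)
    b = (2.0 * v1 - v2) * eps1 + (2.0 * v2 - v1) * eps2
    c = eps1 * eps2
    return _quadratic_mixture_root(a, b, c, eps1, v2)


# ---------------------------------------------------------------------------
# convenience evaluation of the TX-100/saline mixture
# ---------------------------------------------------------------------------

def mixture_eps(
    law: MixingLaw,
    composition: MixtureComposition,
    frequencies: np.ndarray,
    temperature: float = 25.0,
    tx100: DebyeModel = None,
) -> np.ndarray:
    """eps_m of the TX-100/saline mixture on a frequency array."""
    tx100 = tx100 or load_tx100()
    saline = SalineModel(composition.nacl, temperature)
    return mix(law, tx100.eval(frequencies), saline.eval(frequencies),
               composition.v2_saline)


def mixture_spectrum(
    law: MixingLaw,
    composition: MixtureComposition,
    grid: FrequencyGrid,
    temperature: float = 25.0,
    tx100: DebyeModel = None,
) -> DielectricSpectrum:
    """eps_m of the TX-100/saline mixture as a :class:`DielectricSpectrum`."""
    f = grid.frequencies
    return DielectricSpectrum(f, mixture_eps(law, composition, f, temperature, tx100))


# ---------------------------------------------------------------------------
# analytic derivatives with respect to (V2, Sm)
# ---------------------------------------------------------------------------

def _deriv_wrt_v2_and_eps2(law: MixingLaw, eps1, eps2, v2):
    """(d eps_m/d v2, d eps_m/d eps2) for the named law (analytic)."""
    law = MixingLaw(law)
    eps1 = np.asarray(eps1, dtype=complex)
    eps2 = np.asarray(eps2, dtype=complex)
    v1 = 1.0 - v2

    if law is MixingLaw.KRASZEWSKI:
        s1, s2 = np.sqrt(eps1), np.sqrt(eps2)
        s = s1 + v2 * (s2 - s1)
        return 2.0 * s * (s2 - s1), s * v2 / s2
    if law is MixingLaw.LICHTENECKER:
        em = np.exp(v1 * np.log(eps1) + v2 * np.log(eps2))
        return em * (np.log(eps2) - np.log(eps1)), em * v2 / eps2
    if law is MixingLaw.LOOYENGA:
        c = v1 * eps1 ** (1.0 / 3.0) + v2 * eps2 ** (1.0 / 3.0)
        d_v2 = 3.0 * c**2 * (eps2 ** (1.0 / 3.0) - eps1 ** (1.0 / 3.0))
        d_e2 = c**2 * v2 * eps2 ** (-2.0 / 3.0)
        return d_v2, d_e2
    em = mix(law, eps1, eps2, v2)
    if law is MixingLaw.BOTTCHER:
        # F = (em - eps1)(eps2 + 2 em) - 3 v2 em (eps2 - eps1) = 0
        F_em = (eps2 + 2.0 * em) + 2.0 * (em - eps1) - 3.0 * v2 * (eps2 - eps1)
        F_v2 = -3.0 * em * (eps2 - eps1)
        F_e2 = (em - eps1) - 3.0 * v2 * em
    else:  # Bruggeman
        # F = v1 (eps1 - em)(eps2 + 2 em) + v2 (eps2 - em)(eps1 + 2 em) = 0
        F_em = v1 * (-(eps2 + 2.0 * em) + 2.0 * (eps1 - em)) + v2 * (
            -(eps1 + 2.0 * em) + 2.0 * (eps2 - em)
        )
        F_v2 = -(eps1 - em) * (eps2 + 2.0 * em) + (eps2 - em) * (eps1 + 2.0 * em)
        F_e2 = v1 * (eps1 - em) + v2 * (eps1 + 2.0 * em)
    return -F_v2 / F_em, -F_e2 / F_em


def mixture_derivatives(
    law: MixingLaw,
    composition: MixtureComposition,
    grid: FrequencyGrid,
    temperature: float = 25.0,
    tx100: DebyeModel = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frequency (d eps_m/d V2, d eps_m/d Sm) for the TX-100/saline mixture.

    The salinity derivative chains through the analytic d eps2/d S of the
    saline model.  Contract (tested): both components match central finite
    differences of the mixture permittivity to better than 1e-6 relative.
    """
    tx100 = tx100 or load_tx100()
    f = grid.frequencies
    saline = SalineModel(composition.nacl, temperature)
    eps1 = tx100.eval(f)
    eps2 = saline.eval(f)
    d_v2, d_e2 = _deriv_wrt_v2_and_eps2(law, eps1, eps2, composition.v2_saline)
    d_s = d_e2 * saline.eval_salinity_derivative(f)
    return d_v2, d_s
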