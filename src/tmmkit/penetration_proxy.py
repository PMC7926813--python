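"""1D transfer-matrix explorer for field penetration into a layered head.

Normal-incidence plane-wave propagation through a stack of planar,
non-magnetic layers between two semi-infinite media (the coupling medium
on the incidence side, the innermost tissue on the exit side).  This is
a desk-scale, qualitative tool for comparing coupling media and wall
materials — it is not a substitute for full-wave 3D simulation of an
antenna array around an anthropomorphic phantom.

Conventions (matching the rest of the package): eps = eps' - j eps'',
time factor e^{+j w t}; the complex wavenumber k = (w/c) sqrt(eps) then
has a non-positive imaginary part and e^{-j k z} decays in +z.  Wave
impedance eta = eta0 / sqrt(eps).

For the 2x2 amplitude matrices used here the determinant of the full
interface+propagation product equals eta_in/eta_out, which serves as a
reciprocity check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .tissue_dielectrics import EPS0, ValidationError, load_tissue

MU0 = 4.0e-7 * np.pi
C0 = 1.0 / np.sqrt(MU0 * EPS0)
ETA0 = np.sqrt(MU0 / EPS0)

#: 3D-printing plastic of the phantom walls at 1 GHz
ABS_EPS_R = 3.0
ABS_SIGMA_S_PER_M = 0.004


def eps_with_sigma(eps_r: float, sigma: float, f: float) -> complex:
    """eps' - j sigma/(w eps0) at frequency f."""
    return complex(eps_r, -sigma / (2.0 * np.pi * f * EPS0))


def abs_eps(f: float) -> complex:
    """Complex permittivity of the ABS wall material."""
    return eps_with_sigma(ABS_EPS_R, ABS_SIGMA_S_PER_M, f)


def tissue_eps(name: str, f: float) -> complex:
    """Complex permittivity of a vendored tissue at frequency f."""
    return complex(load_tissue(name).eval(np.array([f]))[0])


@dataclass(frozen=True)
class Layer:
    name: str
    thickness_mm: float
    eps: complex

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValidationError(
                f"layer {self.name!r}: thickness must be > 0 mm, got {self.thickness_mm}"
            )
        if self.eps.real <= 0 or self.eps.imag > 1e-9:
            raise ValidationError(f"layer {self.name!r}: permittivity must be passive")


@dataclass(frozen=True)
class LayerStack:
    """Semi-infinite incidence medium | finite layers | semi-infinite exit."""

    incidence_eps: complex
    layers: tuple
    exit_eps: complex

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        for e, side in ((self.incidence_eps, "incidence"), (self.exit_eps, "exit")):
            e = complex(e)
            if e.real <= 0 or e.imag > 1e-9:
                raise ValidationError(f"{side} medium permittivity must be passive")


@dataclass(frozen=True)
class TransferResult:
    """Amplitudes normalized to a unit incident field."""

    reflection: complex
    transmitted: complex
    #: forward/backward E-amplitude pair at the entry of each region,
    #: ordered incidence medium, layers..., exit medium
    interface_amplitudes: tuple
    reflectance: float
    transmittance: float


def _eta_k(eps: complex, w: float) -> Tuple[complex, complex]:
    n = np.sqrt(complex(eps))
    return ETA0 / n, w / C0 * n


def transfer(stack: LayerStack, f: float) -> TransferResult:
    """Solve the layered normal-incidence problem at frequency ``f``.

    Returns the reflection coefficient in the incidence medium, the
    transmitted forward amplitude in the exit medium, and the
    forward/backward amplitude pairs at the entry of every region.
    """
    if f <= 0:
        raise ValidationError(f"frequency must be > 0, got {f}")
    w = 2.0 * np.pi * f
    media = [complex(stack.incidence_eps)] + [l.eps for l in stack.layers] + [
        complex(stack.exit_eps)
    ]
    etas = [_eta_k(e, w)[0] for e in media]
    ks = [_eta_k(e, w)[1] for e in media]

    def interface(i: int, j: int) -> np.ndarray:
        r = (etas[j] - etas[i]) / (etas[j] + etas[i])
        t = 2.0 * etas[j] / (etas[j] + etas[i])
        return np.array([[1.0, r], [r, 1.0]], dtype=complex) / t

    def propagation(i: int) -> np.ndarray:
        d = stack.layers[i - 1].thickness_mm * 1e-3
        ph = 1j * ks[i] * d
        return np.array([[np.exp(ph), 0.0], [0.0, np.exp(-ph)]], dtype=complex)

    # back-substitute from the exit medium ([a, b] = [t, 0])
    n_regions = len(media)
    vec = np.array([1.0, 0.0], dtype=complex)  # un-normalized exit amplitudes
    amps = [vec]
    for i in range(n_regions - 2, 0, -1):
        vec = interface(i, i + 1) @ vec       # amplitudes at right edge of region i
        amps.append(vec)
        vec = propagation(i) @ vec            # amplitudes at left edge of region i
    vec = interface(0, 1) @ vec
    amps.append(vec)
    amps = amps[::-1]

    a0, b0 = amps[0]
    scale = 1.0 / a0  # normalize to unit incident amplitude
    amps = tuple((complex(a * scale), complex(b * scale)) for a, b in amps)
    gamma = amps[0][1]
    t_out = amps[-1][0]

    reflectance = float(abs(gamma) ** 2)
    transmittance = float(
        abs(t_out) ** 2 * np.real(1.0 / etas[-1]) / np.real(1.0 / etas[0])
    )
    return TransferResult(
        reflection=gamma,
        transmitted=t_out,
        interface_amplitudes=amps,
        reflectance=reflectance,
        transmittance=transmittance,
    )


@dataclass(frozen=True)
class CouplingReport:
    """Transmitted amplitude into the exit medium per coupling candidate."""

    couplings: tuple            # complex permittivities tried
    transmitted_abs: tuple      # |t| per coupling
    normalized: tuple           # (|t| - min)/(max - min) display scale
    ranking: tuple              # indices, best first


def compare_coupling(
    layers: Sequence[Layer],
    exit_eps: complex,
    couplings: Sequence[complex],
    f: float,
) -> CouplingReport:
    """Rank coupling media by transmitted amplitude into the exit medium.

    The normalized column maps |t| onto (x - min)/(max - min), the usual
    display normalization for field maps.
    """
    couplings = tuple(complex(c) for c in couplings)
    if len(couplings) < 2:
        raise ValidationError("need at least 2 coupling candidates to compare")
    mags = []
    for c in couplings:
        stack = LayerStack(incidence_eps=c, layers=tuple(layers), exit_eps=exit_eps)
        mags.append(abs(transfer(stack, f).transmitted))
    mags_arr = np.array(mags)
    lo, hi = mags_arr.min(), mags_arr.max()
    norm = (mags_arr - lo) / (hi - lo) if hi > lo else np.ones_like(mags_arr)
    ranking = tuple(int(i) for i in np.argsort(-mags_arr))
    return CouplingReport(
        couplings=couplings,
        transmitted_abs=tuple(float(m) for m in mags),
        normalized=tuple(float(x) for x in norm),
        ranking=ranking,
    )


def head_stack_layers(f: float, skull_mm: float = 7.0, csf_mm: float = 2.0) -> tuple:
    """Skull/CSF layer pair (brain as exit medium) built from the fixtures."""
    return (
        Layer("skull", skull_mm, tissue_eps("bone_cortical", f)),
        Layer("csf", csf_mm, tissue_eps("csf", f)),
    )
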