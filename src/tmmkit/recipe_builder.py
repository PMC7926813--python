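"""Turn a fitted composition into a bench-ready recipe.

A :class:`Recipe` converts the dimensionless composition (saline volume
fraction V2, NaCl concentration in g/L) into masses for a chosen batch
volume, using fixture densities:

* TX-100: 1.07 g/mL at 25 °C (supplier constant, stored with the Debye
  fixture);
* water: 0.997 g/mL at 25 °C.

The saline-phase volume is approximated by the water volume — the volume
change on dissolving NaCl is neglected, consistent with the g/L (grams
per litre of solution) concentration definition at bench accuracy.

Mixtures whose TX-100 volume percentage falls in the closed band
[40, 60] vol% are flagged: at 25 °C such mixtures are viscous and need
the warm-mix procedure (components warmed separately, then mixed and
vigorously stirred, rested at 45 °C until air bubbles vanish).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .mixing_laws import MixtureComposition
from .tissue_dielectrics import ValidationError, tx100_density_g_per_mL

WATER_DENSITY_G_PER_ML = 0.997

#: closed viscosity band in TX-100 vol%
VISCOSITY_BAND_TX_PERCENT = (40.0, 60.0)

#: preparation steps for the TX-100/saline mixtures
PROTOCOL_STEPS = (
    "Place the empty beaker on the balance and tare.",
    "Add the NaCl mass, tare, then add the deionized-water mass "
    "(tare between additions).",
    "Stir with a magnetic bar until the saline solution is homogeneous; "
    "tare the balance again.",
    "Add the TX-100 mass. Warm the TX-100 beforehand in a 45 °C water "
    "bath: the pure liquid is very viscous and must be fluid to pour and "
    "dose accurately.",
    "Stir with the magnetic bar while the beaker sits in the hot water "
    "bath until the mixture is homogeneous.",
    "Store the mixture in a closed container at room temperature, away "
    "from light, for conservation.",
)

VISCOSITY_WARNING = (
    "TX-100 fraction {tx:.1f} vol% lies in the viscous {lo:.0f}-{hi:.0f} vol% "
    "band at 25 °C: warm the components separately, then mix and stir "
    "vigorously, and let the mixture rest at 45 °C until air bubbles "
    "vanish. Expect the largest deviation between design and measurement "
    "here; salt and TX-100 quantities may need experimental adjustment."
)


def viscosity_check(composition: MixtureComposition) -> Optional[str]:
    """Warning string if the TX-100 fraction is in the viscous band, else None.

    The band is the closed interval [40, 60] vol% TX-100 (both endpoints
    included).
    """
    lo, hi = VISCOSITY_BAND_TX_PERCENT
    tx = composition.tx_vol_percent
    if lo <= tx <= hi:
        return VISCOSITY_WARNING.format(tx=tx, lo=lo, hi=hi)
    return None


@dataclass(frozen=True)
class Recipe:
    """Bench recipe: volumes and masses per batch, warnings, protocol."""

    composition: MixtureComposition
    batch_volume_L: float
    tx100_volume_L: float
    saline_volume_L: float
    tx100_mass_g: float
    water_mass_g: float
    nacl_mass_g: float
    warnings: tuple = ()
    protocol: tuple = PROTOCOL_STEPS

    def recovered_composition(self) -> MixtureComposition:
        """Invert masses back to (V2, Sm); identity round-trip (tested)."""
        v2 = self.saline_volume_L / self.batch_volume_L
        nacl = self.nacl_mass_g / self.saline_volume_L if self.saline_volume_L > 0 else 0.0
        return MixtureComposition(v2, nacl)

    def to_dict(self) -> dict:
        return {
            "composition": {
                "v2_saline": self.composition.v2_saline,
                "nacl_g_per_L": self.composition.nacl,
                "tx100_vol_percent": self.composition.tx_vol_percent,
            },
            "batch_volume_L": self.batch_volume_L,
            "tx100_volume_L": self.tx100_volume_L,
            "saline_volume_L": self.saline_volume_L,
            "tx100_mass_g": self.tx100_mass_g,
            "water_mass_g": self.water_mass_g,
            "nacl_mass_g": self.nacl_mass_g,
            "warnings": list(self.warnings),
            "protocol": list(self.protocol),
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def to_text(self) -> str:
        """Human-readable bench sheet."""
        lines = [
            "TX-100 / saline mixture recipe",
            "=" * 34,
            f"batch volume     : {self.batch_volume_L:.3f} L",
            f"TX-100           : {self.composition.tx_vol_percent:.1f} vol%  "
            f"({self.tx100_volume_L:.4f} L, {self.tx100_mass_g:.2f} g)",
            f"saline           : {100 * self.composition.v2_saline:.1f} vol%  "
            f"({self.saline_volume_L:.4f} L)",
            f"  deionized water: {self.water_mass_g:.2f} g",
            f"  NaCl           : {self.nacl_mass_g:.3f} g  "
            f"({self.composition.nacl:.1f} g/L of saline)",
        ]
        if self.warnings:
            lines.append("")
            for w in self.warnings:
                lines.append(f"*** WARNING: {w}")
        lines.append("")
        lines.append("Protocol")
        lines.append("-" * 8)
        for i, step in enumerate(self.protocol, 1):
            lines.append(f"{i}. {step}")
        return "\n".join(lines) + "\n"

    def to_text_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())


def build_recipe(
    composition: MixtureComposition,
    batch_volume_L: float,
    tx100_density: Optional[float] = None,
    water_density: float = WATER_DENSITY_G_PER_ML,
) -> Recipe:
    """Recipe (volumes and masses) for a batch of the given composition."""
    if batch_volume_L <= 0:
        raise ValidationError(f"batch_volume_L must be > 0, got {batch_volume_L}")
    rho_tx = tx100_density if tx100_density is not None else tx100_density_g_per_mL()
    tx_vol = composition.v1_tx * batch_volume_L
    saline_vol = composition.v2_saline * batch_volume_L
    warning = viscosity_check(composition)
    return Recipe(
        composition=composition,
        batch_volume_L=batch_volume_L,
        tx100_volume_L=tx_vol,
        saline_volume_L=saline_vol,
        tx100_mass_g=tx_vol * 1000.0 * rho_tx,
        water_mass_g=saline_vol * 1000.0 * water_density,
        nacl_mass_g=composition.nacl * saline_vol,
        warnings=(warning,) if warning else (),
    )
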