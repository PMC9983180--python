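"""Visual systems: cone sets, abundances, receptor noise and viewing geometry.

Three observers are built in.  Two are modelled prey species of
scorpionfish — the triplefin *Tripterygion delaisi* (trichromat, single cone
at 468 nm, double cones at 517 and 530 nm) and the two-spotted goby
*Pomatoschistus flavescens* (456, 531, 553 nm).  The third is the
scorpionfish itself (*Scorpaena*), a dichromat with single cones at 455 nm
and double cones at 530 nm, used to judge how the animal perceives the
backgrounds it sits on.

Receptor noise follows the receptor-noise-limited convention: the most
abundant cone class has Weber fraction ``nu`` (0.05 here) and scarcer
classes are noisier by the inverse square root of their relative abundance,
``omega_i = nu * sqrt(eta_max / eta_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, WavelengthGrid, govardovskii_sensitivity

__all__ = ["Observer", "builtin_observer", "weber_fractions", "BUILTIN_OBSERVERS"]


@dataclass(frozen=True)
class Observer:
    """A named visual system.

    luminance_cones holds 0-based indices of the cone classes averaged for
    the luminance (achromatic) channel — by default the two longest-wavelength
    (double) cones for a trichromat, the single long cone for a dichromat.
    acuity (cycles/degree) and viewing_distance (cm) drive the acuity blur;
    they may be None for observers never used to filter images.
    """

    name: str
    cone_lambda_max: tuple[float, ...]
    cone_ratio: tuple[float, ...]
    weber_ref: float = 0.05
    luminance_cones: tuple[int, ...] = ()
    acuity_cpd: float | None = None
    viewing_distance_cm: float | None = None

    def __post_init__(self) -> None:
        if len(self.cone_lambda_max) != len(self.cone_ratio):
            raise ValueError("cone_lambda_max and cone_ratio must align")
        if len(self.cone_lambda_max) < 2:
            raise ValueError("an observer needs at least two cone classes")
        if any(l2 <= l1 for l1, l2 in zip(self.cone_lambda_max, self.cone_lambda_max[1:])):
            raise ValueError("cone_lambda_max must be ordered short to long")
        if any(r <= 0 for r in self.cone_ratio):
            raise ValueError("cone abundances must be positive")
        if self.weber_ref <= 0:
            raise ValueError("weber_ref must be positive")
        if not self.luminance_cones:
            object.__setattr__(self, "luminance_cones", self._default_luminance_cones())
        if any(i < 0 or i >= self.n_cones for i in self.luminance_cones):
            raise ValueError("luminance_cones indices out of range")

    def _default_luminance_cones(self) -> tuple[int, ...]:
        n = len(self.cone_lambda_max)
        return (n - 2, n - 1) if n >= 3 else (n - 1,)

    @property
    def n_cones(self) -> int:
        return len(self.cone_lambda_max)

    def sensitivities(self, grid: WavelengthGrid | None = None) -> list[Spectrum]:
        """A1-template spectral sensitivities for each cone class."""
        return [govardovskii_sensitivity(lm, grid) for lm in self.cone_lambda_max]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cone_lambda_max": list(self.cone_lambda_max),
            "cone_ratio": list(self.cone_ratio),
            "weber_ref": self.weber_ref,
            "luminance_cones": list(self.luminance_cones),
            "acuity_cpd": self.acuity_cpd,
            "viewing_distance_cm": self.viewing_distance_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Observer":
        return cls(
            name=d["name"],
            cone_lambda_max=tuple(d["cone_lambda_max"]),
            cone_ratio=tuple(d["cone_ratio"]),
            weber_ref=d.get("weber_ref", 0.05),
            luminance_cones=tuple(d.get("luminance_cones", ())),
            acuity_cpd=d.get("acuity_cpd"),
            viewing_distance_cm=d.get("viewing_distance_cm"),
        )


BUILTIN_OBSERVERS: dict[str, Observer] = {
    # Tripterygion delaisi: sw single cone + mw/lw double cones; the single
    # cone is ~4x scarcer than each double-cone member.
    "triplefin": Observer(
        name="triplefin",
        cone_lambda_max=(468.0, 517.0, 530.0),
        cone_ratio=(0.25, 1.0, 1.0),
        weber_ref=0.05,
        acuity_cpd=7.0,
        viewing_distance_cm=30.0,
    ),
    # Pomatoschistus flavescens: longer-shifted trichromat.
    "goby": Observer(
        name="goby",
        cone_lambda_max=(456.0, 531.0, 553.0),
        cone_ratio=(0.72, 1.0, 0.6),
        weber_ref=0.05,
        acuity_cpd=2.36,
        viewing_distance_cm=30.0,
    ),
    # Scorpaena: dichromat, 1:1 single to double cones.  Used only for
    # between-background contrasts, never to filter images, so no acuity.
    "scorpionfish": Observer(
        name="scorpionfish",
        cone_lambda_max=(455.0, 530.0),
        cone_ratio=(1.0, 1.0),
        weber_ref=0.05,
    ),
}


def builtin_observer(name: str) -> Observer:
    """Look up one of the built-in visual systems by name."""
    try:
        return BUILTIN_OBSERVERS[name]
    except KeyError:
        raise KeyError(
            f"unknown observer {name!r}; available: {sorted(BUILTIN_OBSERVERS)}"
        ) from None


def weber_fractions(obs: Observer) -> np.ndarray:
    """Per-cone Weber fractions omega_i = nu * sqrt(eta_max / eta_i).

    Scale-invariant in the abundances: only relative eta matters, and the
    most abundant class attains omega = nu exactly.
    """
    eta = np.asarray(obs.cone_ratio, dtype=float)
    return obs.weber_ref * np.sqrt(eta.max() / eta)
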