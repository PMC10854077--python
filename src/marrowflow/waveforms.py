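"""Loading waveforms and boundary-condition parameters.

Three boundary data drive the coupled problem over one loading cycle of
period ``T``:

* a sinusoidal compressive displacement on the top solid face,
  ``u(t) = B/2 (sin(2 pi (t - T/4)/T) + 1)``, ranging over [0, B];
* a spring (Robin) traction ``-k (u_solid - U0)`` on the four lateral solid
  faces, standing in for the compliance of surrounding bone;
* a sinusoidal normal pressure ``P(t) = C/2 (sin(2 pi (t - T/4)/T) + 1)`` on
  the six open outer faces of the fluid box.

Defaults: B = 0.8 um, T = 1 s, C = 667 Pa, k = 16e9 N/mm^2 per mm of
displacement.  The printed unit of k is a pressure; it is interpreted as a
spring stiffness per unit area (traction = k * displacement with displacement
in mm), which at this magnitude makes the lateral faces effectively rigid.
The unit string is stored so users can override the interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LoadSpec",
    "displacement_waveform",
    "displacement_rate",
    "pressure_waveform",
    "spring_traction",
]

#: conversion of the supported k unit strings to SI (Pa per m of displacement)
_K_UNIT_TO_SI = {
    # N/mm^2 of traction per mm of displacement = 1e6 Pa / 1e-3 m
    "N/mm^2/mm": 1e9,
    "N/mm^3": 1e9,
    "Pa/m": 1.0,
    "N/m^3": 1.0,
}


@dataclass
class LoadSpec:
    """Loading-waveform and lateral-spring parameters.

    B : displacement amplitude, um.  T : period, s.  C : pressure amplitude,
    Pa.  k_value/k_units : lateral spring stiffness per unit area.  U0 :
    initial lateral-surface displacement, um.
    """

    B: float = 0.8
    T: float = 1.0
    C: float = 667.0
    k_value: float = 16e9
    k_units: str = "N/mm^2/mm"
    U0: float = 0.0

    def __post_init__(self) -> None:
        if self.B < 0 or self.T <= 0 or self.C < 0 or self.k_value < 0:
            raise ValueError("require B >= 0, T > 0, C >= 0, k >= 0")
        if self.k_units not in _K_UNIT_TO_SI:
            raise ValueError(
                f"unknown k_units {self.k_units!r}; supported: {sorted(_K_UNIT_TO_SI)}"
            )

    @property
    def k_si(self) -> float:
        """Spring stiffness in Pa per metre of displacement."""
        return self.k_value * _K_UNIT_TO_SI[self.k_units]


def displacement_waveform(t, spec: LoadSpec):
    """Top-face displacement u(t) in um; 0 at t=0, maximum B at t=T/2."""
    t = np.asarray(t, dtype=float)
    return spec.B / 2.0 * (np.sin(2.0 * np.pi * (t - spec.T / 4.0) / spec.T) + 1.0)


def displacement_rate(t, spec: LoadSpec):
    """Analytic du/dt in um/s; maximal (B*pi/T) at t = T/4."""
    t = np.asarray(t, dtype=float)
    return (spec.B * np.pi / spec.T) * np.cos(2.0 * np.pi * (t - spec.T / 4.0) / spec.T)


def pressure_waveform(t, spec: LoadSpec):
    """Outer-boundary normal pressure P(t) in Pa; range [0, C]."""
    t = np.asarray(t, dtype=float)
    return spec.C / 2.0 * (np.sin(2.0 * np.pi * (t - spec.T / 4.0) / spec.T) + 1.0)


def spring_traction(u_solid, spec: LoadSpec):
    """Spring-foundation traction (Pa) opposing lateral displacement.

    ``u_solid`` is the current lateral-surface displacement in um; the return
    is ``-k (u_solid - U0)`` with the stiffness converted to SI.
    """
    u_m = (np.asarray(u_solid, dtype=float) - spec.U0) * 1e-6
    return -spec.k_si * u_m
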