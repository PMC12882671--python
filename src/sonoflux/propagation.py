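"""Phenomenological acoustic propagation in solid-state fermentation piles.

A moist tea pile is a porous, heterogeneous medium; full poroelastic
treatment is replaced here by a power-law intensity attenuation

    alpha(f) = alpha_ref * (f / f_ref)^n,     I(z) = I0 exp(-alpha z)

calibrated to two (frequency, 90%-attenuation-depth) anchors, plus a
single-pass multilayer interface model with intensity transmission
T = 4 Z1 Z2 / (Z1 + Z2)^2 and a minimal monotone biofilm-impedance law
Z_eff = Z (1 + kappa * rho_EPS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AttenuationModel",
    "LayerSpec",
    "calibrate_attenuation",
    "penetration_depth",
    "intensity_profile",
    "multilayer_transmission",
    "interface_transmission",
    "biofilm_transmission",
]


@dataclass
class AttenuationModel:
    """Power-law frequency dependence of the intensity attenuation
    coefficient."""

    alpha_ref: float  # m^-1 at f_ref
    f_ref: float  # kHz
    exponent: float  # dimensionless n >= 0

    def __post_init__(self) -> None:
        if self.alpha_ref <= 0 or self.f_ref <= 0:
            raise ValueError("alpha_ref and f_ref must be positive")
        if self.exponent < 0:
            raise ValueError("exponent must be nonnegative")

    def alpha(self, f_khz):
        f = np.asarray(f_khz, dtype=float)
        out = self.alpha_ref * (f / self.f_ref) ** self.exponent
        return out if out.ndim else float(out)


@dataclass
class LayerSpec:
    """One layer of the pile stack."""

    thickness: float  # m
    impedance: float  # Pa s m^-1, characteristic acoustic impedance
    alpha: float  # internal intensity attenuation, m^-1

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.impedance <= 0 or self.alpha < 0:
            raise ValueError("layer parameters must be positive")


def calibrate_attenuation(anchors: Sequence[tuple[float, float]]) -> AttenuationModel:
    """Calibrate the power law from (frequency kHz, d90 m) anchors.

    With two anchors the exponent is n = ln(d1/d2) / ln(f2/f1) and
    alpha_ref = ln 10 / d90(f_ref) at the first anchor frequency.  More than
    two anchors are fitted by least squares on the log-log relation.
    """
    anchors = list(anchors)
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors")
    f = np.array([a[0] for a in anchors], dtype=float)
    d = np.array([a[1] for a in anchors], dtype=float)
    if np.unique(f).size < 2:
        raise ValueError("anchor frequencies must be distinct")
    if np.any(f <= 0) or np.any(d <= 0):
        raise ValueError("anchors must be positive")
    # alpha proportional to 1/d90 at fixed attenuation fraction
    slope, intercept = np.polyfit(np.log(f), np.log(math.log(10.0) / d), 1)
    f_ref = f[0]
    alpha_ref = math.exp(intercept + slope * math.log(f_ref))
    return AttenuationModel(alpha_ref=alpha_ref, f_ref=f_ref, exponent=slope)


def penetration_depth(model: AttenuationModel, f_khz, fraction: float = 0.9):
    """Depth at which intensity has dropped by ``fraction``:
    d = -ln(1 - fraction) / alpha(f)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    out = -np.log(1.0 - fraction) / model.alpha(f_khz)
    return out if np.ndim(out) else float(out)


def intensity_profile(model: AttenuationModel, f_khz, depths, i0: float = 1.0):
    """Exponential intensity decay I(z) = I0 exp(-alpha(f) z)."""
    z = np.asarray(depths, dtype=float)
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    if np.any(z < 0):
        raise ValueError("depths must be nonnegative")
    return i0 * np.exp(-model.alpha(f_khz) * z)


def interface_transmission(z1: float, z2: float) -> float:
    """Normal-incidence intensity transmission 4 Z1 Z2 / (Z1 + Z2)^2."""
    if z1 <= 0 or z2 <= 0:
        raise ValueError("impedances must be positive")
    return 4.0 * z1 * z2 / (z1 + z2) ** 2


def multilayer_transmission(layers: Sequence[LayerSpec], f_khz: float | None = None):
    """Single-pass transmission through a layer stack.

    Returns ``(per_interface_T, cumulative)`` where ``per_interface_T`` lists
    the intensity transmission at each of the len(layers)-1 internal
    interfaces and ``cumulative`` multiplies interface losses with internal
    exponential absorption exp(-alpha_j d_j).  Multiple internal reflections
    are ignored.  ``f_khz`` is accepted for interface with frequency-aware
    callers; the layer alphas are taken as given.
    """
    if not layers:
        raise ValueError("need at least one layer")
    per_interface = [
        interface_transmission(a.impedance, b.impedance)
        for a, b in zip(layers[:-1], layers[1:])
    ]
    absorption = math.exp(-sum(layer.alpha * layer.thickness for layer in layers))
    cumulative = float(np.prod(per_interface)) * absorption
    return per_interface, cumulative


def biofilm_transmission(base: LayerSpec, eps_density: float, kappa: float,
                         adjacent_impedance: float | None = None):
    """Effective impedance and interface transmission of a biofilm-coated
    layer.

    Extracellular polymeric substances raise the effective impedance
    linearly, Z_eff = Z (1 + kappa rho_EPS); transmission is evaluated
    against ``adjacent_impedance`` (defaulting to the uncoated layer, so the
    interface starts matched and T falls monotonically as EPS accumulates).
    """
    if eps_density < 0:
        raise ValueError("EPS density must be nonnegative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    z_adj = base.impedance if adjacent_impedance is None else adjacent_impedance
    z_eff = base.impedance * (1.0 + kappa * eps_density)
    return z_eff, interface_transmission(z_adj, z_eff)
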