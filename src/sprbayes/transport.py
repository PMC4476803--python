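"""Mass-transport physics for SPR flow cells.

Analyte delivery from the bulk flow to the sensor surface is characterised by
the mass-transport coefficient ``kM``.  Under laminar flow in a rectangular
flow cell, ``kM`` scales with the cube root of the volumetric flow rate and
with the two-thirds power of the analyte diffusion coefficient:

    kM_linear = C_kM * (D^2 * F / (h^2 * w * l))^(1/3)        [m/s]

where the dimensionless geometry factor

    C_kM = 1.47 * (1 - (l1/l2)^(2/3)) / (1 - l1/l2)

accounts for the position of the optical detection window (``l1``, ``l2``
measured from the flow-cell inlet).  ``C_kM`` decreases monotonically from
1.47 (detection window starting at the inlet) to 0.98 (vanishingly short
window at the outlet).

For use with response-unit (RU) sensorgrams, ``kM_linear`` is rescaled so
that a 1 M bulk concentration drives a response flux of ``kM`` RU/s:

    kM [RU/(M s)] = kM_linear * MW * G * 1e6

with ``MW`` the analyte molecular weight in g/mol and ``G`` the instrument
response factor in RU·mm²/ng (≈1000 for proteins).  The factor 1e6 collects
the unit conversions M → mol/m³ (×1000) and g/m² → ng/mm² (×1000).

The degree of transport limitation for a given surface is summarised by the
mass-transport limit coefficient MTLC = ka·Rmax/kM: below 1 the binding is
kinetically limited, between 1 and 100 partially transport-limited, above
100 fully transport-limited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "FlowCellGeometry",
    "AnalyteProperties",
    "TransportContext",
    "ckm_factor",
    "diffusion_layer_height",
    "estimate_diffusion_coefficient",
    "mass_transport_coefficient",
    "mass_transport_limit_coefficient",
]

# Physical constants (SI)
BOLTZMANN = 1.380649e-23        # J/K
AVOGADRO = 6.02214076e23        # 1/mol

#: Effective specific volume (m^3/kg) used to convert molecular weight to a
#: hydrodynamic radius.  This is a calibrated effective value — larger than a
#: bare protein partial specific volume because it absorbs hydration and
#: shape effects — chosen once so that a 201.2 Da analyte (the sulfonamide
#: inhibitor 4-CBS) at 298.15 K in water (eta = 8.9e-4 Pa·s) has
#: D = 4.76e-10 m²/s.  User-overridable per analyte.
DEFAULT_VBAR = 1.7174e-3

#: Instrument response factor, RU·mm²/ng; ~1000 for proteins.
DEFAULT_G = 1000.0


class GeometryError(ValueError):
    """Invalid flow-cell geometry (e.g. detection window l1 >= l2)."""


@dataclass(frozen=True)
class FlowCellGeometry:
    """Rectangular flow-cell geometry in SI units.

    Attributes
    ----------
    h, w, l : float
        Chamber height, width and length (m).
    l1, l2 : float
        Distance from the inlet to the start / end of the detection area (m).
    F : float
        Volumetric flow rate (m³/s).
    """

    h: float
    w: float
    l: float
    F: float
    l1: float = 0.0
    l2: Optional[float] = None

    def __post_init__(self):
        if self.l2 is None:
            object.__setattr__(self, "l2", self.l)
        for name in ("h", "w", "l", "F"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.l1 < 0:
            raise GeometryError("l1 must be nonnegative")
        if not self.l1 < self.l2:
            raise GeometryError(f"require l1 < l2 (got l1={self.l1}, l2={self.l2})")
        if self.l2 > self.l * (1 + 1e-12):
            raise GeometryError(f"detection window end l2={self.l2} exceeds chamber length l={self.l}")

    @classmethod
    def from_instrument(
        cls,
        h_mm: float,
        w_mm: float,
        l_mm: float,
        flow_ul_min: float,
        l1_mm: float = 0.0,
        l2_mm: Optional[float] = None,
    ) -> "FlowCellGeometry":
        """Build from instrument-native units (mm and µl/min).

        The conversions are exact: 1 mm = 1e-3 m and
        1 µl/min = 1e-9/60 m³/s (so 50 µl/min = 8.333...e-10 m³/s).
        """
        return cls(
            h=h_mm * 1e-3,
            w=w_mm * 1e-3,
            l=l_mm * 1e-3,
            F=flow_ul_min * 1e-9 / 60.0,
            l1=l1_mm * 1e-3,
            l2=None if l2_mm is None else l2_mm * 1e-3,
        )


@dataclass(frozen=True)
class AnalyteProperties:
    """Analyte physical properties used to resolve a diffusion coefficient.

    Attributes
    ----------
    MW : float
        Molecular weight (Da = g/mol).
    D : float, optional
        Diffusion coefficient (m²/s).  When absent it is estimated from MW
        via the Stokes-Einstein relation with a calibrated effective
        specific volume.
    T : float
        Absolute temperature (K).
    eta : float
        Solvent dynamic viscosity (Pa·s).
    vbar : float
        Effective specific volume converting MW to hydrodynamic radius
        (m³/kg); see :data:`DEFAULT_VBAR`.
    """

    MW: float
    D: Optional[float] = None
    T: float = 298.15
    eta: float = 8.9e-4
    vbar: float = DEFAULT_VBAR

    def __post_init__(self):
        if self.MW <= 0:
            raise ValueError("MW must be strictly positive")
        if self.D is not None and self.D <= 0:
            raise ValueError("D must be strictly positive when given")
        for name in ("T", "eta", "vbar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TransportContext:
    """Resolved transport quantities for one analyte/flow-cell pairing."""

    hdiff: float       # diffusion-layer height (m)
    kM_linear: float   # transport coefficient (m/s)
    kM: float          # transport coefficient rescaled to RU/(M s)
    G: float           # response factor (RU mm^2/ng)
    CkM: float         # detection-window geometry factor (dimensionless)
    D: float = field(default=0.0)   # diffusion coefficient used (m^2/s)


def ckm_factor(l1: float, l2: float) -> float:
    """Detection-window geometry factor C_kM = 1.47·(1−(l1/l2)^⅔)/(1−l1/l2).

    ``l1`` and ``l2`` are the distances from the flow-cell inlet to the
    start and end of the detection area.  The factor is 1.47 for a window
    starting at the inlet (l1 = 0) and decreases monotonically towards the
    limit 1.47·(2/3) = 0.98 as l1 → l2.
    """
    if l1 < 0:
        raise GeometryError("l1 must be nonnegative")
    if not l1 < l2:
        raise GeometryError(f"require l1 < l2 (got l1={l1}, l2={l2})")
    ratio = l1 / l2
    if ratio > 1 - 1e-12:
        # continuous limit by l'Hopital: 1.47 * (2/3)
        return 1.47 * 2.0 / 3.0
    return 1.47 * (1.0 - ratio ** (2.0 / 3.0)) / (1.0 - ratio)


def diffusion_layer_height(D: float, geom: FlowCellGeometry) -> float:
    """Characteristic diffusion-layer height hdiff = (D·h²·w·l/F)^(1/3), in m.

    This is the effective thickness of the depleted layer above the sensor
    surface in the two-compartment picture; only the two-compartment
    reference model depends on it.
    """
    if D <= 0:
        raise ValueError("D must be strictly positive")
    return (D * geom.h ** 2 * geom.w * geom.l / geom.F) ** (1.0 / 3.0)


def estimate_diffusion_coefficient(props: AnalyteProperties) -> float:
    """Estimate D (m²/s) from molecular weight by Stokes-Einstein.

    The hydrodynamic radius is taken as the radius of a sphere of mass MW
    and effective specific volume ``vbar``:

        r = (3·MW·vbar / (4π·NA))^(1/3),   D = kB·T / (6π·eta·r)

    so D ∝ MW^(-1/3) and D ∝ 1/eta.  With the default calibrated ``vbar``
    a 201.2 Da analyte gives D = 4.76e-10 m²/s at 298.15 K in water.
    """
    mw_kg = props.MW * 1e-3  # Da = g/mol -> kg/mol
    r = (3.0 * mw_kg * props.vbar / (4.0 * math.pi * AVOGADRO)) ** (1.0 / 3.0)
    return BOLTZMANN * props.T / (6.0 * math.pi * props.eta * r)


def mass_transport_coefficient(
    props: AnalyteProperties,
    geom: FlowCellGeometry,
    G: float = DEFAULT_G,
) -> TransportContext:
    """Resolve the full transport context (hdiff, kM_linear, kM) for a run.

    ``kM_linear = C_kM · (D²·F/(h²·w·l))^(1/3)`` in m/s is rescaled to
    response units as ``kM = kM_linear · MW · G · 1e6`` RU/(M·s): a 1 M bulk
    concentration (1000 mol/m³) delivers ``kM_linear·1000·MW`` g/(m²·s) =
    ``kM_linear·1000·MW·1000`` ng/(mm²·s), which the instrument reports as
    ``G`` RU per ng/mm².  With the default G = 1000 this reduces to the
    familiar ``kM_linear · MW · 1e9``.
    """
    if G <= 0:
        raise ValueError("G must be strictly positive")
    D = props.D if props.D is not None else estimate_diffusion_coefficient(props)
    ckm = ckm_factor(geom.l1, geom.l2)
    kM_linear = ckm * (D ** 2 * geom.F / (geom.h ** 2 * geom.w * geom.l)) ** (1.0 / 3.0)
    kM = kM_linear * props.MW * G * 1e6
    return TransportContext(
        hdiff=diffusion_layer_height(D, geom),
        kM_linear=kM_linear,
        kM=kM,
        G=G,
        CkM=ckm,
        D=D,
    )


def mass_transport_limit_coefficient(ka: float, Rmax: float, kM: float) -> float:
    """Mass-transport limit coefficient MTLC = ka·Rmax/kM (dimensionless).

    The free-ligand level is taken at its maximum Rmax, matching the usual
    worst-case convention.  MTLC < 1: kinetically limited; 1–100: partial
    transport limitation (the regime this package targets); > 100:
    transport-limited.
    """
    if kM <= 0:
        raise ValueError("kM must be strictly positive")
    if ka <= 0 or Rmax <= 0:
        raise ValueError("ka and Rmax must be strictly positive")
    return ka * Rmax / kM
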