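"""Physical and dimensionless parameter sets for the active-droplet swarm model.

The swarm is a thin viscous film of cells (effective surface tension ``kappa``,
effective viscosity ``eta``) driven by a chemotactic active stress of magnitude
``xi`` and fed by a bacterial lawn that sources a diffusible chemoattractant.
All dynamics are integrated in dimensionless variables; this module owns the
mapping between the two descriptions.

Nondimensional groups (with height scale ``H``, length scale ``L``, time scale
``T``, bacteria scale ``B`` and chemoattractant concentration scale ``C``):

====================  =====================================================
group                 definition
====================  =====================================================
``Ca_kappa``          ``eta * L**4 / (kappa * H**3 * T)``   (passive)
``Ca_xi``             ``xi * H * T / (eta * L**2)``         (active)
``slip``              ``slip_length / H``
``peclet``            ``L**2 / (chemo_diffusivity * T)``
``growth``            ``growth_rate * T``
``consumption``       ``consumption_rate * T``
``production``        ``chemo_production * B * T / C``
``decay``             ``chemo_decay * T``
``sensing``           ``sensing_threshold * L / C``
``saturation``        ``saturation_const * L / C``
``precursor``         ``precursor_height / H``
====================  =====================================================

``Ca_kappa`` is the ratio of the viscous scale ``eta*L/T`` to the capillary
(Laplace) pressure scale ``kappa*H**3/L**3`` acting over the film; it is
inversely proportional to the surface tension, so stiff (high ``kappa``)
swarms have small ``Ca_kappa``.  ``Ca_xi`` compares the active
(Marangoni-like) flux to the reference flux ``H*L/T`` and is proportional to
the activity ``xi``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace, asdict
from pathlib import Path

import yaml

__all__ = [
    "PhysicalParams",
    "DimensionlessParams",
    "nondimensionalize",
    "redimensionalize",
    "reference_params",
    "load_params",
    "save_params",
]


class InvalidParameterError(ValueError):
    """A parameter violates its positivity/ordering invariant."""


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional material, kinetic and scale parameters.

    Units are stated per field; any consistent unit system works as long as
    it is used throughout.  Defaults are the calibrated reference set (see
    ``reference_params``).
    """

    kappa: float  #: effective surface tension [force/length]
    eta: float  #: effective viscosity [pressure * time]
    xi: float  #: activity magnitude (chemotactic active-stress scale) [pressure]
    slip_length: float  #: Navier slip length at the floor [length]
    growth_rate: float  #: maximal proliferation rate [1/time]
    consumption_rate: float  #: bacteria consumption per unit swarm height [1/time]
    chemo_production: float  #: chemoattractant production per unit bacteria [conc/time]
    chemo_diffusivity: float  #: [length**2/time]
    chemo_decay: float  #: [1/time]
    sensing_threshold: float  #: minimal detectable |grad c| [conc/length]
    saturation_const: float  #: receptor-saturation gradient scale [conc/length]
    precursor_height: float  #: wetting-film height regularizing dry regions [length]
    height_scale: float  #: characteristic swarm height H [length]
    length_scale: float  #: characteristic horizontal length L [length]
    time_scale: float  #: characteristic time T [time]
    bacteria_scale: float = 1.0  #: reference lawn level B [amount/length]
    conc_scale: float = 1.0  #: reference chemoattractant concentration C [conc]

    def __post_init__(self) -> None:
        nonneg = ("sensing_threshold", "slip_length")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in nonneg:
                if v < 0:
                    raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
            elif not v > 0:
                raise InvalidParameterError(f"{f.name} must be > 0, got {v}")
        if self.precursor_height > 0.05 * self.height_scale:
            raise InvalidParameterError(
                "precursor_height must be << height_scale "
                f"(<= 0.05*H = {0.05 * self.height_scale}, got {self.precursor_height})"
            )


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless groups actually used by the solver.

    ``contact_angle`` is the equilibrium contact angle of the wetting
    potential in rescaled units; the reference configuration keeps it at 1 so
    that a relaxed passive droplet of volume V has length sqrt(6 V).
    """

    Ca_kappa: float
    Ca_xi: float
    slip: float
    peclet: float
    growth: float
    consumption: float
    production: float
    decay: float
    sensing: float
    saturation: float
    precursor: float
    growth_half_sat: float = 0.2  #: half-saturation of the growth response, in lawn units
    contact_angle: float = 1.0

    def __post_init__(self) -> None:
        if not self.Ca_kappa > 0:
            raise InvalidParameterError(f"Ca_kappa must be > 0, got {self.Ca_kappa}")
        if self.Ca_xi < 0:
            raise InvalidParameterError(f"Ca_xi must be >= 0, got {self.Ca_xi}")
        for name in ("slip", "sensing", "growth", "consumption", "production"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("peclet", "decay", "saturation", "precursor",
                     "growth_half_sat", "contact_angle"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")


def nondimensionalize(p: PhysicalParams, *, growth_half_sat: float = 0.2,
                      contact_angle: float = 1.0) -> DimensionlessParams:
    """Form the dimensionless groups of a physical parameter set.

    The groupings are documented in the module docstring; doubling ``kappa``
    halves ``Ca_kappa``, and ``xi = 0`` gives ``Ca_xi = 0``.
    """
    H, L, T = p.height_scale, p.length_scale, p.time_scale
    B, C = p.bacteria_scale, p.conc_scale
    return DimensionlessParams(
        Ca_kappa=p.eta * L**4 / (p.kappa * H**3 * T),
        Ca_xi=p.xi * H * T / (p.eta * L**2),
        slip=p.slip_length / H,
        peclet=L**2 / (p.chemo_diffusivity * T),
        growth=p.growth_rate * T,
        consumption=p.consumption_rate * T,
        production=p.chemo_production * B * T / C,
        decay=p.chemo_decay * T,
        sensing=p.sensing_threshold * L / C,
        saturation=p.saturation_const * L / C,
        precursor=p.precursor_height / H,
        growth_half_sat=growth_half_sat,
        contact_angle=contact_angle,
    )


def redimensionalize(dp: DimensionlessParams, *, eta: float, height_scale: float,
                     length_scale: float, time_scale: float,
                     bacteria_scale: float = 1.0,
                     conc_scale: float = 1.0) -> PhysicalParams:
    """Invert ``nondimensionalize`` given the viscosity and the five scales.

    The dimensionless groups fix every material parameter once ``eta`` and
    the scales are chosen; the round trip
    ``nondimensionalize(redimensionalize(dp, ...))`` recovers ``dp`` to
    machine precision.
    """
    H, L, T = height_scale, length_scale, time_scale
    return PhysicalParams(
        kappa=eta * L**4 / (dp.Ca_kappa * H**3 * T),
        eta=eta,
        xi=dp.Ca_xi * eta * L**2 / (H * T),
        slip_length=dp.slip * H,
        growth_rate=dp.growth / T,
        consumption_rate=dp.consumption / T,
        chemo_production=dp.production * conc_scale / (bacteria_scale * T),
        chemo_diffusivity=L**2 / (dp.peclet * T),
        chemo_decay=dp.decay / T,
        sensing_threshold=dp.sensing * conc_scale / L,
        saturation_const=dp.saturation * conc_scale / L,
        precursor_height=dp.precursor * H,
        height_scale=H,
        length_scale=L,
        time_scale=T,
        bacteria_scale=bacteria_scale,
        conc_scale=conc_scale,
    )


# Calibrated reference configuration.  The dimensionless groups were fixed by
# matching the line-track simulation to the observed clump-shedding period and
# spacing (see swarmdrop.simulate.calibrate and docs/methods.md); the scales
# then map one dimensionless length/time unit onto the laboratory values.
_REFERENCE_DIMLESS = dict(
    Ca_kappa=0.10,
    Ca_xi=25.0,
    slip=0.15,
    peclet=1.0 / 36.0,
    growth=0.065,
    consumption=4.0,
    production=36.0,
    decay=36.0,
    sensing=0.05,
    saturation=0.2,
    precursor=0.05,
    growth_half_sat=0.2,
    contact_angle=1.0,
)

# One dimensionless length/time unit in laboratory units, fixed by matching
# the simulated clump spacing and shedding period to the line-track
# measurements (1.25 mm between clumps, one clump per 4.6 h).
_REFERENCE_SCALES = dict(
    eta=1.0e2,           # Pa s; sets the stress scale, not the dynamics
    height_scale=100.0,  # um (boundary threshold 30 um = 0.3 units)
    length_scale=25.6,   # um
    time_scale=0.13731,  # h
)


def reference_dimensionless() -> DimensionlessParams:
    """The calibrated dimensionless reference configuration."""
    return DimensionlessParams(**_REFERENCE_DIMLESS)


def reference_params() -> PhysicalParams:
    """Calibrated reference parameters in physical units (um, h, Pa s)."""
    return redimensionalize(reference_dimensionless(), **_REFERENCE_SCALES)


def save_params(p: PhysicalParams | DimensionlessParams, path: str | Path) -> None:
    """Write a parameter set to a YAML file (kind recorded in a header key)."""
    d = {"kind": type(p).__name__}
    d.update(asdict(p))
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_params(path: str | Path) -> PhysicalParams | DimensionlessParams:
    """Read a parameter set written by ``save_params``."""
    d = yaml.safe_load(Path(path).read_text())
    kind = d.pop("kind", "PhysicalParams")
    cls = {"PhysicalParams": PhysicalParams, "DimensionlessParams": DimensionlessParams}[kind]
    return cls(**d)


def with_friction_factor(dp: DimensionlessParams, factor: float) -> DimensionlessParams:
    """Scale the floor friction by ``factor`` (slip scales as 1/factor).

    Navier slip and floor friction are reciprocal descriptions of the same
    boundary condition, so a friction sweep x1/4 ... x4 maps to slip factors
    x4 ... x1/4.
    """
    if factor <= 0:
        raise InvalidParameterError("friction factor must be > 0")
    return replace(dp, slip=dp.slip / factor)


def reference_config_path() -> Path:
    """Path of the bundled reference parameter YAML file."""
    return Path(__file__).parent / "data" / "reference_params.yaml"
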