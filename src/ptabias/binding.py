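"""Plasma-protein-binding relationships.

Two layers of description coexist. The mechanistic layer models binding to a
finite pool of plasma proteins with capacity Bmax and dissociation constant
Kd: Ctot = Cfree + Bmax*Cfree/(Kd + Cfree), which in the linear regime
(Kd >> Cfree) collapses to Ctot = Cfree*(1 + Bmax/Kd) and yields the unbound
fraction fu = Kd/(Bmax + Kd). The operational layer is the familiar
Cfree = fu * Ctot, valid only as bookkeeping once fu is known.

The distinction matters because the free steady-state concentration under
continuous infusion is INF_rate / CL_free and so does not depend on binding
at all (for low-extraction drugs): binding variability propagates to total,
never to free, concentrations. That one-way dependence is what the scenario
engine's bias results rest on, and it is encoded here in the signature of
:func:`css_infusion`, which admits no binding argument.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BindingParameters",
    "InfusionRegimen",
    "ctot_saturable",
    "ctot_linear",
    "fu_linear",
    "cfree_from_ctot",
    "ctot_from_cfree",
    "css_infusion",
]


@dataclass(frozen=True)
class BindingParameters:
    """Saturable-binding parameters: capacity ``bmax`` and affinity ``kd``.

    Both are concentrations in the same units as the drug concentrations they
    are combined with (e.g. mg/L).
    """

    bmax: float
    kd: float

    def __post_init__(self) -> None:
        if self.bmax < 0:
            raise ValueError(f"bmax must be non-negative, got {self.bmax}")
        if not (self.kd > 0):
            raise ValueError(f"kd must be positive, got {self.kd}")


@dataclass(frozen=True)
class InfusionRegimen:
    """Constant-rate IV infusion: ``rate`` (mass/kg/time), ``cl_free`` (vol/kg/time)."""

    rate: float
    cl_free: float

    def __post_init__(self) -> None:
        if not (self.rate > 0):
            raise ValueError(f"infusion rate must be positive, got {self.rate}")
        if not (self.cl_free > 0):
            raise ValueError(f"free clearance must be positive, got {self.cl_free}")


def _check_conc(c: float, name: str) -> None:
    if c < 0:
        raise ValueError(f"{name} must be non-negative, got {c}")


def ctot_saturable(cfree: float, params: BindingParameters) -> float:
    """Total concentration under saturable binding.

    Ctot = Cfree + Bmax*Cfree/(Kd + Cfree). Monotone increasing in cfree and
    always >= cfree.
    """
    _check_conc(cfree, "cfree")
    return cfree + params.bmax * cfree / (params.kd + cfree)


def ctot_linear(cfree: float, params: BindingParameters) -> float:
    """Total concentration in the linear (Kd >> Cfree) regime: Cfree*(1 + Bmax/Kd)."""
    _check_conc(cfree, "cfree")
    return cfree * (1.0 + params.bmax / params.kd)


def fu_linear(params: BindingParameters) -> float:
    """Unbound fraction under linear binding: Kd/(Bmax + Kd), in (0, 1]."""
    return params.kd / (params.bmax + params.kd)


def _check_fu(fu: float) -> None:
    if not (0 < fu <= 1):
        raise ValueError(f"fu must lie in (0, 1], got {fu}")


def cfree_from_ctot(ctot: float, fu: float) -> float:
    """Operational free concentration: Cfree = fu * Ctot."""
    _check_conc(ctot, "ctot")
    _check_fu(fu)
    return fu * ctot


def ctot_from_cfree(cfree: float, fu: float) -> float:
    """Operational total concentration: Ctot = Cfree / fu. Inverse of
    :func:`cfree_from_ctot`."""
    _check_conc(cfree, "cfree")
    _check_fu(fu)
    return cfree / fu


def css_infusion(regimen: InfusionRegimen) -> float:
    """Free steady-state concentration under constant infusion: rate / CL_free.

    Deliberately takes no binding parameters: free exposure is independent of
    plasma-protein binding for low-extraction drugs. Algebraically the same
    quotient as the dose-based fAUC computation, solved in different units.
    """
    return regimen.rate / regimen.cl_free
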