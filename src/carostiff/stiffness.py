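"""Local carotid stiffness indices from per-measurement (Ds, Dd, Ps, Pd).

The five quantities computed here are the standard single-site indices of the
common carotid artery:

* ``β`` — stiffness index, ``ln(Ps/Pd) / ((Ds − Dd)/Dd)`` (dimensionless);
* ``Ep`` — pressure–strain elastic modulus, ``(Ps − Pd) / ((Ds − Dd)/Dd)`` in kPa;
* ``AC`` — arterial (lumen-area) compliance, ``π(Ds² − Dd²) / (4 ΔP)`` in mm²/kPa;
* ``PWVβ`` — one-point pulse wave velocity via the Bramwell–Hill-type relation
  ``sqrt(β · Pd / (2ρ))`` with Pd in Pa, in m/s;
* ``DC`` — distensibility coefficient, ``((Ds² − Dd²)/Dd²) / ΔP`` in 1/kPa,
  the common scale the other measures are compared against.

Diameters are end-systolic (Ds) and end-diastolic (Dd) lumen diameters in mm;
pressures are brachial systolic/diastolic in mmHg as measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import PressureError, QualityError, StrainError

#: mmHg → kPa conversion factor.
MMHG_TO_KPA = 0.133322
#: mmHg → Pa conversion factor.
MMHG_TO_PA = 133.322
#: Default blood mass density, kg/m³.
DEFAULT_BLOOD_DENSITY = 1050.0


@dataclass(frozen=True)
class PressurePair:
    """A systolic/diastolic brachial pressure pair in mmHg."""

    ps: float
    pd: float

    def __post_init__(self) -> None:
        if not (self.ps > self.pd > 0.0):
            raise PressureError(
                f"require Ps > Pd > 0, got Ps={self.ps}, Pd={self.pd}"
            )

    @property
    def pulse_pressure_kpa(self) -> float:
        return (self.ps - self.pd) * MMHG_TO_KPA

    @property
    def pd_pa(self) -> float:
        return self.pd * MMHG_TO_PA


@dataclass(frozen=True)
class StiffnessPanel:
    """One measurement's stiffness indices plus the inputs they came from."""

    beta: float
    ep: float  # kPa
    ac: float  # mm²/kPa
    pwv_beta: float  # m/s
    dc: float  # 1/kPa
    ds: float  # mm
    dd: float  # mm
    ps: float  # mmHg
    pd: float  # mmHg
    rho: float  # kg/m³


def _strain(ds: float, dd: float) -> float:
    if not (ds > dd > 0.0):
        raise StrainError(f"require Ds > Dd > 0, got Ds={ds}, Dd={dd}")
    return (ds - dd) / dd


def compute_beta(ds: float, dd: float, p: PressurePair) -> float:
    """Stiffness index β = ln(Ps/Pd) / ((Ds − Dd)/Dd)."""
    return math.log(p.ps / p.pd) / _strain(ds, dd)


def compute_ep(ds: float, dd: float, p: PressurePair) -> float:
    """Pressure–strain elastic modulus Ep = ΔP / strain, in kPa."""
    return p.pulse_pressure_kpa / _strain(ds, dd)


def compute_ac(ds: float, dd: float, p: PressurePair) -> float:
    """Arterial compliance AC = π(Ds² − Dd²)/(4 ΔP), in mm²/kPa.

    Unlike β/Ep this is well defined (and zero) at Ds == Dd.
    """
    if not (ds >= dd > 0.0):
        raise StrainError(f"require Ds >= Dd > 0, got Ds={ds}, Dd={dd}")
    return math.pi * (ds * ds - dd * dd) / (4.0 * p.pulse_pressure_kpa)


def compute_pwv_beta(
    beta: float, pd_mmhg: float, rho: float = DEFAULT_BLOOD_DENSITY
) -> float:
    """One-point pulse wave velocity PWVβ = sqrt(β · Pd / (2ρ)), Pd in Pa."""
    if beta < 0.0 or pd_mmhg <= 0.0 or rho <= 0.0:
        raise StrainError(
            f"require beta >= 0, Pd > 0, rho > 0; got {beta}, {pd_mmhg}, {rho}"
        )
    return math.sqrt(beta * pd_mmhg * MMHG_TO_PA / (2.0 * rho))


def compute_dc(ds: float, dd: float, p: PressurePair) -> float:
    """Distensibility coefficient DC = ((Ds² − Dd²)/Dd²)/ΔP, in 1/kPa."""
    if not (ds >= dd > 0.0):
        raise StrainError(f"require Ds >= Dd > 0, got Ds={ds}, Dd={dd}")
    return ((ds * ds - dd * dd) / (dd * dd)) / p.pulse_pressure_kpa


def panel_from_diameters(
    ds: float,
    dd: float,
    p: PressurePair,
    rho: float = DEFAULT_BLOOD_DENSITY,
) -> StiffnessPanel:
    """All five indices from a single (Ds, Dd, Ps, Pd) tuple."""
    beta = compute_beta(ds, dd, p)
    return StiffnessPanel(
        beta=beta,
        ep=compute_ep(ds, dd, p),
        ac=compute_ac(ds, dd, p),
        pwv_beta=compute_pwv_beta(beta, p.pd, rho),
        dc=compute_dc(ds, dd, p),
        ds=ds,
        dd=dd,
        ps=p.ps,
        pd=p.pd,
        rho=rho,
    )


def compute_panel(
    waveform,
    p: PressurePair,
    rho: float = DEFAULT_BLOOD_DENSITY,
    *,
    per_beat: bool = False,
) -> StiffnessPanel:
    """Average stiffness indices over the accepted beats of a waveform.

    Parameters
    ----------
    waveform
        A beat-segmented :class:`~carostiff.echotrack.DistensionWaveform`
        (any object exposing ``beat_ds``, ``beat_dd`` and ``accepted`` arrays).
    p
        Brachial pressure pair used for every beat of the measurement.
    rho
        Blood density in kg/m³.
    per_beat
        Default (``False``) averages Ds and Dd over accepted beats and computes
        the indices once on the averages, which is how a device reporting
        "average stiffness indices" from beat-by-beat parameters behaves.
        ``True`` computes the indices beat-by-beat and averages the indices
        instead; the two differ at second order in beat-to-beat variability.
    """
    accepted = np.asarray(waveform.accepted, dtype=bool)
    if accepted.size == 0 or not accepted.any():
        raise QualityError("no accepted beats; measurement must be repeated")
    ds_beats = np.asarray(waveform.beat_ds, dtype=float)[accepted]
    dd_beats = np.asarray(waveform.beat_dd, dtype=float)[accepted]
    if per_beat:
        panels = [
            panel_from_diameters(float(ds), float(dd), p, rho)
            for ds, dd in zip(ds_beats, dd_beats)
        ]
        return StiffnessPanel(
            beta=float(np.mean([q.beta for q in panels])),
            ep=float(np.mean([q.ep for q in panels])),
            ac=float(np.mean([q.ac for q in panels])),
            pwv_beta=float(np.mean([q.pwv_beta for q in panels])),
            dc=float(np.mean([q.dc for q in panels])),
            ds=float(ds_beats.mean()),
            dd=float(dd_beats.mean()),
            ps=p.ps,
            pd=p.pd,
            rho=rho,
        )
    return panel_from_diameters(float(ds_beats.mean()), float(dd_beats.mean()), p, rho)
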