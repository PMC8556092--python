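"""Monitor calibration and Co-60-based absorbed-dose conversion.

Three relations tie a chamber's charge reading to absorbed dose to water in
a carbon-ion beam calibrated against Co-60:

* monitor calibration ``K(E) = D_meas * A / (S_(E)x * MU)`` — particles per
  monitor unit from a plateau dose measurement (``S`` is the mass stopping
  power at the measurement depth; the MeV-to-joule conversion makes the
  result a particle count);
* absorbed dose at the effective point
  ``D_w(P_eff) = M_corr * k_TP * N_w,Co-60 * K_Q``;
* beam-quality factor
  ``K_Q = [(w/e)_C12 * s_w,air^carbon] / [(w/e)_Co60 * (L/rho)_w,air]``
  converting the Co-60 calibration to the carbon beam (``w/e`` mean energies
  per unit charge, stopping-power ratios water/air; the Co-60 ratio is the
  Spencer-Attix restricted one).

Physics constants (``w/e`` values, stopping-power ratios) are user-supplied
inputs; the package bundles no authoritative defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MEV_TO_JOULE",
    "CalibrationInputs",
    "QualityFactors",
    "monitor_calibration",
    "k_tp",
    "beam_quality_kq",
    "absorbed_dose_peff",
]

#: 1 MeV in joules (CODATA exact).
MEV_TO_JOULE = 1.602176634e-13

T0_CELSIUS = 20.0
P0_HPA = 1013.25
_ZERO_CELSIUS = 273.2  # convention used by the k_TP correction


@dataclass(frozen=True)
class CalibrationInputs:
    """Inputs of the monitor-calibration and dose-conversion relations."""

    D_meas_gy: float        # dose measured in the phantom plateau, Gy
    S_mev_cm2_g: float      # mass stopping power at the measurement depth
    MU: float               # monitor units delivered
    A_cm2: float            # homogeneously irradiated area, cm^2
    M_corr_c: float         # corrected chamber charge, C
    N_w_co60_gy_c: float    # Co-60 absorbed-dose-to-water calibration, Gy/C
    T_celsius: float = T0_CELSIUS
    P_hpa: float = P0_HPA

    def __post_init__(self) -> None:
        for name in ("D_meas_gy", "S_mev_cm2_g", "MU", "A_cm2", "M_corr_c", "N_w_co60_gy_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.T_celsius <= -_ZERO_CELSIUS:
            raise ValueError("temperature below absolute zero")
        if self.P_hpa <= 0:
            raise ValueError("pressure must be > 0")


@dataclass(frozen=True)
class QualityFactors:
    """w/e values and stopping-power ratios entering K_Q."""

    we_c12: float    # effective w/e for carbon incl. fragments, J/C
    we_co60: float   # w/e for Co-60, J/C
    spr_carbon: float  # water/air stopping-power ratio for carbon
    spr_co60: float    # restricted water/air ratio (Spencer-Attix), Co-60

    def __post_init__(self) -> None:
        for name in ("we_c12", "we_co60", "spr_carbon", "spr_co60"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def monitor_calibration(
    D_meas_gy: float, S_mev_cm2_g: float, MU: float, A_cm2: float
) -> float:
    """Monitor calibration K(E), particles per monitor unit.

    ``K = D_meas * A / (S * MU)`` with the stopping power converted from
    MeV cm^2/g to J cm^2/kg (Gy cm^2 per particle), the only dimensionally
    consistent arrangement of the four quantities.
    """
    for name, val in (
        ("D_meas_gy", D_meas_gy),
        ("S_mev_cm2_g", S_mev_cm2_g),
        ("MU", MU),
        ("A_cm2", A_cm2),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be > 0")
    # S in Gy cm^2 per particle: MeV cm^2/g -> J cm^2/g -> J cm^2/kg
    s_gy_cm2 = S_mev_cm2_g * MEV_TO_JOULE * 1000.0
    return D_meas_gy * A_cm2 / (s_gy_cm2 * MU)


def k_tp(
    T_celsius: float,
    P_hpa: float,
    T0_celsius: float = T0_CELSIUS,
    P0_hpa: float = P0_HPA,
) -> float:
    """Air-density correction ``(273.2 + T)/(273.2 + T0) * (P0 / P)``.

    Equal to 1 exactly at the reference conditions (20 degC, 1013.25 hPa by
    default).
    """
    if P_hpa <= 0:
        raise ValueError("pressure must be > 0")
    return (_ZERO_CELSIUS + T_celsius) / (_ZERO_CELSIUS + T0_celsius) * (P0_hpa / P_hpa)


def beam_quality_kq(q: QualityFactors) -> float:
    """Beam-quality factor K_Q = (we_c12 * spr_carbon)/(we_co60 * spr_co60)."""
    return (q.we_c12 * q.spr_carbon) / (q.we_co60 * q.spr_co60)


def absorbed_dose_peff(
    M_corr_c: float,
    N_w_co60_gy_c: float,
    K_Q: float,
    k_tp_factor: float = 1.0,
) -> float:
    """Absorbed dose to water at P_eff, Gy: ``M_corr * k_TP * N_w * K_Q``.

    ``k_tp_factor`` is exposed separately because protocols differ on
    whether the reported charge already includes the air-density correction;
    pass 1.0 (default) if ``M_corr_c`` is already fully corrected.
    """
    for name, val in (
        ("M_corr_c", M_corr_c),
        ("N_w_co60_gy_c", N_w_co60_gy_c),
        ("K_Q", K_Q),
        ("k_tp_factor", k_tp_factor),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be > 0")
    return M_corr_c * k_tp_factor * N_w_co60_gy_c * K_Q
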