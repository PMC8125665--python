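"""Severity ordinates for lignocellulose pretreatment.

Hydrothermal and acid pretreatments of biomass are conventionally summarised
by a single log-scale "severity" ordinate that folds time and temperature
into one number:

    SF  = log10( t * exp((T - T_ref) / 14.75) )          (severity factor)
    CSF = SF - pH                                        (combined severity)

For organosolv fractionation the solvent itself does chemical work, so the
severity is extended with solvent (and optionally catalyst) concentration
terms, each credited with a fitted order::

    CSF_ext = (T - T_ref)/omega + ln t + m ln C_sol + n ln C_cat

with ``t`` in minutes, concentrations in mol/L and natural logarithms.  For
formic-acid (FA) fractionation the acid is solvent and catalyst at once, so
the catalyst term is folded into the solvent term (n = 0) and ``T_ref`` is
taken as 70 degC, the low end of the operating window.

Operating liquor composition is reported in the lab as FA weight percent;
the severity formula wants mol/L, so a small density table (wt% -> g/mL at
ambient temperature) performs the conversion ``C = 1000 * rho * w / M_FA``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "FORMIC_ACID_MOLAR_MASS",
    "ConfigurationError",
    "DensityLookupError",
    "DensityTable",
    "DEFAULT_DENSITY_TABLE",
    "FractionationCondition",
    "SeverityConstants",
    "SEVERITY_PRESETS",
    "severity_factor",
    "combined_severity_factor",
    "wtpct_to_molarity",
    "csf_ext_general",
    "csf_ext_fa",
]

#: Molar mass of formic acid (HCOOH), g/mol.
FORMIC_ACID_MOLAR_MASS = 46.03

#: Empirical temperature scale (degC) in the classical severity factor.
SEVERITY_TEMPERATURE_SCALE = 14.75

#: Conventional reference temperature for SF / CSF (dilute-acid tradition).
DEFAULT_SF_T_REF = 100.0

#: Reference temperature for FA fractionation severity (low end of the
#: 80-107 degC operating window).
DEFAULT_FA_T_REF = 70.0


class ConfigurationError(ValueError):
    """A required field or setting is missing or inconsistent."""


class DensityLookupError(LookupError):
    """No density is tabulated for the requested FA weight fraction."""


@dataclass(frozen=True)
class DensityTable:
    """Aqueous formic-acid solution densities keyed by weight percent.

    Parameters
    ----------
    densities_g_per_ml
        Mapping ``{wt_percent: density}`` with densities in g/mL.  Keys are
        exact: a dataset may only use FA levels present in the table.
    molar_mass_g_per_mol
        Molar mass used for the mol/L conversion (formic acid by default).
    """

    densities_g_per_ml: Mapping[float, float]
    molar_mass_g_per_mol: float = FORMIC_ACID_MOLAR_MASS

    def __post_init__(self) -> None:
        if not self.densities_g_per_ml:
            raise ConfigurationError("density table must not be empty")
        for wt, rho in self.densities_g_per_ml.items():
            if not (0.9 < rho < 1.3):
                raise ConfigurationError(
                    f"density {rho} g/mL at {wt} wt% is outside the plausible "
                    "(0.9, 1.3) g/mL range for aqueous formic acid"
                )

    def density(self, weight_fraction: float) -> float:
        """Return the tabulated density (g/mL) for a mass fraction in (0, 1]."""
        wt_percent = 100.0 * weight_fraction
        for key, rho in self.densities_g_per_ml.items():
            if math.isclose(float(key), wt_percent, abs_tol=1e-9):
                return rho
        avail = ", ".join(f"{float(k):g}%" for k in self.densities_g_per_ml)
        raise DensityLookupError(
            f"no density tabulated for {wt_percent:g} wt% formic acid; "
            f"available: {avail}"
        )

    def molarity(self, weight_fraction: float) -> float:
        """Convert an FA mass fraction to mol/L via the tabulated density."""
        return wtpct_to_molarity(weight_fraction, self)

    @classmethod
    def from_json(cls, path) -> "DensityTable":
        """Load a ``{wt_percent: density_g_per_ml}`` JSON mapping."""
        with open(path) as fh:
            raw = json.load(fh)
        return cls({float(k): float(v) for k, v in raw.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({f"{float(k):g}": v for k, v in self.densities_g_per_ml.items()}, fh, indent=2)


#: Ambient-temperature densities of aqueous formic acid at the four liquor
#: strengths of the reference design.  User-overridable via config.
DEFAULT_DENSITY_TABLE = DensityTable(
    {60.0: 1.131, 70.0: 1.153, 80.0: 1.174, 90.0: 1.192}
)


@dataclass(frozen=True)
class FractionationCondition:
    """One fractionation run's operating point.

    Internally temperature is degC, FA content a mass fraction in (0, 1],
    and time minutes; the :meth:`from_lab_units` constructor accepts the
    lab-sheet units (wt%, hours).
    """

    temperature_c: float
    fa_weight_fraction: float
    time_min: float
    ph: float | None = None
    catalyst_molarity: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.temperature_c <= 250.0):
            raise ValueError(
                f"temperature {self.temperature_c} degC outside [0, 250]"
            )
        if not (0.0 < self.fa_weight_fraction <= 1.0):
            raise ValueError(
                f"FA weight fraction {self.fa_weight_fraction} outside (0, 1]"
            )
        if not self.time_min > 0.0:
            raise ValueError(f"time {self.time_min} min must be positive")

    @classmethod
    def from_lab_units(
        cls,
        temperature_c: float,
        fa_wt_percent: float,
        time_h: float,
        ph: float | None = None,
        catalyst_molarity: float | None = None,
    ) -> "FractionationCondition":
        """Build a condition from lab units: FA in wt%, time in hours."""
        return cls(
            temperature_c=temperature_c,
            fa_weight_fraction=fa_wt_percent / 100.0,
            time_min=time_h * 60.0,
            ph=ph,
            catalyst_molarity=catalyst_molarity,
        )


@dataclass(frozen=True)
class SeverityConstants:
    """Constants (T_ref, omega, m[, n]) defining a CSF_ext convention.

    ``omega`` is the severity temperature scale in degC (related to a
    reduced activation energy), ``m`` and ``n`` the fitted orders of the
    solvent and catalyst concentration terms.
    """

    t_ref_c: float
    omega: float
    m: float
    n: float = 0.0

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.m < 0 or self.n < 0:
            raise ValueError("concentration orders m, n must be nonnegative")


#: Named CSF_ext conventions.  The ``*-table1`` pair is fitted from pooled
#: xylan-plus-lignin solubilization and reproduces the packaged 16-run
#: reference severity table; the ``eq7``/``eq8`` pair is the alternative
#: printed convention, which does NOT reproduce that table and is shipped
#: for completeness only.
SEVERITY_PRESETS: dict[str, SeverityConstants] = {
    "arrhenius-table1": SeverityConstants(DEFAULT_FA_T_REF, omega=14.54, m=12.10),
    "logistic-table1": SeverityConstants(DEFAULT_FA_T_REF, omega=13.91, m=12.52),
    "arrhenius-eq7": SeverityConstants(DEFAULT_FA_T_REF, omega=16.795, m=12.165),
    "logistic-eq8": SeverityConstants(DEFAULT_FA_T_REF, omega=16.32, m=12.67),
}


def severity_factor(
    condition: FractionationCondition, t_ref_c: float = DEFAULT_SF_T_REF
) -> float:
    """Classical severity factor SF = log10(t * exp((T - T_ref)/14.75)).

    ``t`` in minutes, base-10 logarithm (severity-ordinate tradition).
    """
    if not condition.time_min > 0:
        raise ValueError("time must be positive")
    return math.log10(
        condition.time_min
        * math.exp((condition.temperature_c - t_ref_c) / SEVERITY_TEMPERATURE_SCALE)
    )


def combined_severity_factor(
    condition: FractionationCondition, t_ref_c: float = DEFAULT_SF_T_REF
) -> float:
    """Combined severity factor CSF = SF - pH.

    The acidity credit is subtracted from the log-severity (the Chum
    convention), not inside the logarithm.
    """
    if condition.ph is None:
        raise ConfigurationError(
            "combined severity factor requires the condition's pH"
        )
    return severity_factor(condition, t_ref_c) - condition.ph


def wtpct_to_molarity(
    weight_fraction: float, density_table: DensityTable = DEFAULT_DENSITY_TABLE
) -> float:
    """Convert an FA mass fraction to molarity: 1000 * rho * w / M_FA."""
    if not (0.0 < weight_fraction <= 1.0):
        raise ValueError(
            f"weight fraction {weight_fraction} outside (0, 1]"
        )
    rho = density_table.density(weight_fraction)
    return 1000.0 * rho * weight_fraction / density_table.molar_mass_g_per_mol


def csf_ext_general(
    condition: FractionationCondition,
    constants: SeverityConstants,
    density_table: DensityTable = DEFAULT_DENSITY_TABLE,
) -> float:
    """Extended combined severity with solvent and catalyst terms.

    CSF_ext = (T - T_ref)/omega + ln t + m ln C_sol + n ln C_cat, natural
    logs, ``t`` in minutes, concentrations in mol/L.  The catalyst term is
    only evaluated when ``n > 0``.
    """
    c_sol = wtpct_to_molarity(condition.fa_weight_fraction, density_table)
    value = (
        (condition.temperature_c - constants.t_ref_c) / constants.omega
        + math.log(condition.time_min)
        + constants.m * math.log(c_sol)
    )
    if constants.n > 0:
        if condition.catalyst_molarity is None or condition.catalyst_molarity <= 0:
            raise ValueError(
                "catalyst order n > 0 requires a positive catalyst molarity"
            )
        value += constants.n * math.log(condition.catalyst_molarity)
    return value


def csf_ext_fa(
    condition: FractionationCondition,
    constants: SeverityConstants,
    density_table: DensityTable = DEFAULT_DENSITY_TABLE,
) -> float:
    """FA-specific extended severity: (T - T_ref)/omega + m ln C_FA + ln t.

    Formic acid acts as solvent and catalyst at once, so the catalyst term
    is absorbed into the solvent order and ``n`` is ignored (treated as 0).
    """
    c_fa = wtpct_to_molarity(condition.fa_weight_fraction, density_table)
    return (
        (condition.temperature_c - constants.t_ref_c) / constants.omega
        + constants.m * math.log(c_fa)
        + math.log(condition.time_min)
    )
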