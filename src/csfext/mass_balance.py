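"""Mass-balance accounting: compositions to solubilization fractions.

A fractionation run is characterized in the lab by the solid yield SY
(fraction of initial dry mass recovered as pretreated solid) and the
composition of that solid (mass fractions of glucan, xylan, lignin, formyl
groups).  The degree of solubilization of a component is then

    alpha = 1 - SY * content / initial_fraction

i.e. one minus the mass of the component remaining in the solid relative to
its mass in the feedstock.  Pooled ("xylan plus lignin") and total-biomass
variants follow from the same balance.  Enzymatic glucan conversion (EGC)
converts released glucose back to anhydroglucan equivalents with the
standard 162/180 = 0.9 anhydro correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "FeedstockComposition",
    "DEFAULT_FEEDSTOCK",
    "CompositionRecord",
    "component_solubilization",
    "pooled_solubilization",
    "total_solubilization",
    "enzymatic_glucan_conversion",
]

#: Anhydro correction: one glucan unit (162 g/mol) yields one glucose (180 g/mol).
ANHYDRO_GLUCAN_FACTOR = 162.0 / 180.0

#: Out-of-range alpha beyond this margin triggers a warning before clamping.
CLAMP_WARN_MARGIN = 0.02


@dataclass(frozen=True)
class FeedstockComposition:
    """Initial dry-basis mass fractions of the feedstock.

    Defaults are for depithed sugarcane bagasse: 43.4% glucan, 24.4% xylan,
    1.2% arabinan, 2.51% acetyl, 24.2% Klason lignin, 2.88% acid-soluble
    lignin.
    """

    glucan: float = 0.434
    xylan: float = 0.244
    arabinan: float = 0.012
    acetyl: float = 0.0251
    klason_lignin: float = 0.242
    acid_soluble_lignin: float = 0.0288

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"feedstock fraction {name}={v} outside [0, 1]")

    def lignin_basis(self, basis: str = "klason") -> float:
        """Initial lignin fraction: Klason-only (default) or total lignin."""
        if basis == "klason":
            return self.klason_lignin
        if basis == "total":
            return self.klason_lignin + self.acid_soluble_lignin
        raise ValueError(f"unknown lignin basis {basis!r} (use 'klason' or 'total')")

    def xylan_basis(self, basis: str = "xylan_only") -> float:
        """Initial xylan fraction: xylan-only (default) or xylan + arabinan."""
        if basis == "xylan_only":
            return self.xylan
        if basis == "with_arabinan":
            return self.xylan + self.arabinan
        raise ValueError(
            f"unknown xylan basis {basis!r} (use 'xylan_only' or 'with_arabinan')"
        )

    def initial_fraction(
        self, component: str, lignin_basis: str = "klason", xylan_basis: str = "xylan_only"
    ) -> float:
        if component == "glucan":
            return self.glucan
        if component == "xylan":
            return self.xylan_basis(xylan_basis)
        if component == "lignin":
            return self.lignin_basis(lignin_basis)
        raise ValueError(f"unknown component {component!r}")


DEFAULT_FEEDSTOCK = FeedstockComposition()


@dataclass(frozen=True)
class CompositionRecord:
    """Measured composition of one run's pretreated solid.

    ``contents`` maps component name (glucan, xylan, lignin, formyl) to its
    mass fraction of the pretreated solid; ``egc`` optionally maps a
    hydrolysis-time label (e.g. "6h", "72h") to the measured enzymatic
    glucan conversion, stored as data only.
    """

    run_id: str
    solid_yield: float
    contents: Mapping[str, float]
    egc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.solid_yield <= 1.0):
            raise ValueError(f"solid yield {self.solid_yield} outside (0, 1]")
        total = 0.0
        for name, c in self.contents.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"content {name}={c} outside [0, 1]")
            total += c
        # independent assays can slightly over-close the balance; tolerate a
        # few percent with a warning, reject anything worse
        if total > 1.05:
            raise ValueError(f"contents sum to {total:.4f} > 1.05")
        if total > 1.0 + 1e-9:
            warnings.warn(
                f"run {self.run_id}: contents sum to {total:.4f} > 1 "
                "(measurement over-closure)",
                stacklevel=3,
            )


def _clamp(alpha: float, label: str) -> float:
    if alpha < -CLAMP_WARN_MARGIN or alpha > 1.0 + CLAMP_WARN_MARGIN:
        warnings.warn(
            f"{label}: solubilization {alpha:.4f} outside [0, 1] by more than "
            f"{CLAMP_WARN_MARGIN}; clamped (check the basis or the measurement)",
            stacklevel=3,
        )
    return min(max(alpha, 0.0), 1.0)


def component_solubilization(
    record: CompositionRecord,
    feedstock: FeedstockComposition = DEFAULT_FEEDSTOCK,
    component: str = "xylan",
    lignin_basis: str = "klason",
    xylan_basis: str = "xylan_only",
) -> float:
    """alpha = 1 - SY * content / initial_fraction for one component."""
    if component not in record.contents:
        raise ValueError(f"run {record.run_id}: no measured content for {component!r}")
    initial = feedstock.initial_fraction(component, lignin_basis, xylan_basis)
    if initial <= 0.0:
        raise ValueError(f"initial fraction of {component} must be positive")
    alpha = 1.0 - record.solid_yield * record.contents[component] / initial
    return _clamp(alpha, f"run {record.run_id} {component}")


def pooled_solubilization(
    record: CompositionRecord,
    feedstock: FeedstockComposition = DEFAULT_FEEDSTOCK,
    lignin_basis: str = "klason",
    xylan_basis: str = "xylan_only",
) -> float:
    """Xylan-plus-lignin solubilization, treating the pair as one pseudo-soluble fraction."""
    for comp in ("xylan", "lignin"):
        if comp not in record.contents:
            raise ValueError(f"run {record.run_id}: no measured content for {comp!r}")
    initial = feedstock.xylan_basis(xylan_basis) + feedstock.lignin_basis(lignin_basis)
    retained = record.solid_yield * (record.contents["xylan"] + record.contents["lignin"])
    return _clamp(1.0 - retained / initial, f"run {record.run_id} xylan_plus_lignin")


def total_solubilization(record: CompositionRecord) -> float:
    """Total biomass solubilization: 1 - solid yield."""
    return 1.0 - record.solid_yield


def enzymatic_glucan_conversion(glucose_released: float, glucan_loaded: float) -> float:
    """EGC = 0.9 * glucose / glucan (anhydro correction 162/180), capped at 1."""
    if glucan_loaded <= 0.0:
        raise ValueError("glucan loading must be positive")
    if glucose_released < 0.0:
        raise ValueError("released glucose cannot be negative")
    egc = ANHYDRO_GLUCAN_FACTOR * glucose_released / glucan_loaded
    if egc > 1.0:
        warnings.warn(
            f"EGC {egc:.4f} exceeds 1 (more glucose than loaded glucan); capped",
            stacklevel=2,
        )
        egc = 1.0
    return egc
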