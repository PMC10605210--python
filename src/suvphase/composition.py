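"""Lipid formulations, Lo/Ld phase partitions, and the DOTAP charge split.

A vesicle membrane made of DOPC:DPPC:Chol can demix into a tightly packed,
cholesterol/DPPC-rich liquid-ordered (Lo) phase and a loosely packed,
DOPC-rich liquid-disordered (Ld) phase.  When part of the DOPC is replaced
by the cationic lipid DOTAP, the positive charge partitions unevenly between
the two phases: DOTAP, whose acyl chains resemble DOPC's, accumulates in the
Ld phase.  The quantity this module computes from a formulation is the
fraction of the vesicle's total charge carried by each phase, which downstream
modules use to distribute the electrostatic force over the vesicle surface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "MembraneComposition",
    "builtin_composition",
    "charge_fraction_ld",
    "BUILTIN_NAMES",
]

_TOTAL_TOL = 1e-9
_PHASE_TOL = 5e-3  # tabulated per-phase rows are rounded


@dataclass(frozen=True)
class MembraneComposition:
    """A named lipid formulation with its Lo/Ld phase partition.

    Parameters
    ----------
    name:
        Formulation label (e.g. ``"PAT3"``).
    total_fractions:
        Overall molar fraction per lipid species; must sum to 1.
    a_D:
        Area fraction of the vesicle surface covered by the Lo phase,
        in [0, 1].  0 denotes a single-phase (homogeneous) membrane.
    ld_fractions, lo_fractions:
        Molar fractions *within* each phase.  ``None`` for single-phase
        membranes.  Each mapping sums to 1 within rounding tolerance.
    """

    name: str
    total_fractions: Mapping[str, float]
    a_D: float
    ld_fractions: Mapping[str, float] | None = None
    lo_fractions: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        total = sum(self.total_fractions.values())
        if abs(total - 1.0) > _TOTAL_TOL:
            raise ValueError(
                f"total_fractions of {self.name!r} sum to {total}, expected 1"
            )
        if not 0.0 <= self.a_D <= 1.0:
            raise ValueError(f"a_D must lie in [0, 1], got {self.a_D}")
        for label, fracs in (("ld", self.ld_fractions), ("lo", self.lo_fractions)):
            if fracs is not None:
                s = sum(fracs.values())
                if abs(s - 1.0) > _PHASE_TOL:
                    raise ValueError(
                        f"{label}_fractions of {self.name!r} sum to {s}, "
                        f"expected 1 within {_PHASE_TOL}"
                    )

    @property
    def is_phase_separated(self) -> bool:
        return self.ld_fractions is not None and self.lo_fractions is not None

    # --- structured-text round trip -------------------------------------

    def to_yaml(self) -> str:
        """Serialize to a YAML document (key -> fraction mappings)."""
        doc = {
            "name": self.name,
            "total_fractions": dict(self.total_fractions),
            "a_D": self.a_D,
        }
        if self.is_phase_separated:
            doc["ld_fractions"] = dict(self.ld_fractions)
            doc["lo_fractions"] = dict(self.lo_fractions)
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str | io.TextIOBase) -> "MembraneComposition":
        if hasattr(text, "read"):
            text = text.read()
        doc = yaml.safe_load(text)
        return cls(
            name=doc["name"],
            total_fractions=doc["total_fractions"],
            a_D=float(doc["a_D"]),
            ld_fractions=doc.get("ld_fractions"),
            lo_fractions=doc.get("lo_fractions"),
        )


# Overall formulations.  The three patchy (PAT) formulations carry 15 mol%
# DOTAP substituted for DOPC in a DOPC:DPPC:Chol base mixture; 0.6 mol%
# Rho-PE is the fluorescent reporter.  Values are stored verbatim as
# tabulated (per-phase rows are rounded and tolerate a small closure error
# rather than being renormalized, so the 67.15% PAT3 charge split comes
# out exactly).
_BUILTINS: dict[str, MembraneComposition] = {}


def _register(comp: MembraneComposition) -> None:
    _BUILTINS[comp.name] = comp


_register(
    MembraneComposition(
        name="Homo",
        total_fractions={"DOPC": 0.994, "DPPC": 0.0, "Chol": 0.0,
                         "DOTAP": 0.0, "RhoPE": 0.006},
        a_D=0.0,
    )
)
_register(
    MembraneComposition(
        name="PAT1",
        total_fractions={"DOPC": 0.444, "DPPC": 0.20, "Chol": 0.20,
                         "DOTAP": 0.15, "RhoPE": 0.006},
        a_D=0.108,
        ld_fractions={"DOTAP": 0.1667, "DOPC": 0.4933, "DPPC": 0.16, "Chol": 0.18},
        lo_fractions={"DOTAP": 0.0556, "DOPC": 0.1644, "DPPC": 0.43, "Chol": 0.35},
    )
)
_register(
    MembraneComposition(
        name="PAT2",
        total_fractions={"DOPC": 0.269, "DPPC": 0.425, "Chol": 0.15,
                         "DOTAP": 0.15, "RhoPE": 0.006},
        a_D=0.3457,
        ld_fractions={"DOTAP": 0.2291, "DOPC": 0.4109, "DPPC": 0.29, "Chol": 0.07},
        lo_fractions={"DOTAP": 0.0465, "DOPC": 0.0835, "DPPC": 0.61, "Chol": 0.26},
    )
)
_register(
    MembraneComposition(
        name="PAT3",
        total_fractions={"DOPC": 0.094, "DPPC": 0.50, "Chol": 0.25,
                         "DOTAP": 0.15, "RhoPE": 0.006},
        a_D=0.7037,
        ld_fractions={"DOTAP": 0.4180, "DOPC": 0.2620, "DPPC": 0.24, "Chol": 0.08},
        lo_fractions={"DOTAP": 0.0861, "DOPC": 0.0539, "DPPC": 0.57, "Chol": 0.29},
    )
)

BUILTIN_NAMES = tuple(_BUILTINS)


def builtin_composition(name: str) -> MembraneComposition:
    """Return one of the built-in formulations (Homo, PAT1, PAT2, PAT3)."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown composition {name!r}; known: {', '.join(BUILTIN_NAMES)}"
        ) from None


def charge_fraction_ld(comp: MembraneComposition) -> float:
    """Area-weighted share of the vesicle's total DOTAP (hence charge) in Ld.

    With per-phase DOTAP concentrations ``c_Ld``, ``c_Lo`` and Lo area
    fraction ``a_D``, the Ld phase carries

        f_Ld = c_Ld (1 - a_D) / [c_Ld (1 - a_D) + c_Lo a_D].

    The complementary Lo share is ``1 - f_Ld`` exactly.  The dye lipid is
    charge-neutral and plays no role here.

    Raises
    ------
    ValueError
        If the composition has no phase partition or if both phases have
        zero DOTAP (the split is then undefined).
    """
    if not comp.is_phase_separated:
        raise ValueError(
            f"composition {comp.name!r} is single-phase; the Ld charge "
            "fraction is undefined"
        )
    c_ld = comp.ld_fractions.get("DOTAP", 0.0)
    c_lo = comp.lo_fractions.get("DOTAP", 0.0)
    w_ld = c_ld * (1.0 - comp.a_D)
    w_lo = c_lo * comp.a_D
    denom = w_ld + w_lo
    if denom <= 0.0:
        raise ValueError(
            f"composition {comp.name!r} carries no DOTAP in either phase; "
            "charge split undefined"
        )
    return w_ld / denom
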