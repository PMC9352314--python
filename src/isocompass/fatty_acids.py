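"""Fatty-acid nomenclature and methyl-ester atom bookkeeping.

Fatty acids are named either by shorthand ``"C:D"`` / ``"C:Dn-x"``
(acyl carbons : double bonds, optionally with the omega position of the
first double bond) or by a registered trivial name (LIN, ALA, DHA, ...).
Atom counts refer to the fatty acid *methyl ester* (FAME) actually
measured by GC-IRMS: esterification with methanol adds one carbon and a
3-H methyl group, which is why every per-mil value coming off the
instrument must later be mass-balance corrected (see
:mod:`isocompass.calibration`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "FattyAcid",
    "FattyAcidRegistry",
    "DEFAULT_REGISTRY",
    "CORE_PANEL",
    "BRAIN_PANEL",
    "parse_fa_name",
]


@dataclass(frozen=True)
class FattyAcid:
    """One fatty acid identity with FAME atom counts.

    Attributes
    ----------
    code : str
        Canonical short name, e.g. ``"16:0"``, ``"18:2n-6"``, ``"LIN"``.
    carbons : int
        Acyl carbon count (the fatty acid itself, not the ester).
    double_bonds : int
        Number of C=C double bonds.
    omega_class : str
        ``"n-3"``, ``"n-6"``, ``"n-9"``, ``"saturated"`` or ``"other"``.
    """

    code: str
    carbons: int
    double_bonds: int
    omega_class: str = "other"

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"{self.code}: need at least 2 acyl carbons")
        if self.double_bonds < 0 or 2 * self.double_bonds > self.carbons:
            raise ValueError(f"{self.code}: impossible double-bond count")

    @property
    def c_count_fame(self) -> int:
        """Carbon atoms in the methyl ester: acyl carbons + 1 from methanol."""
        return self.carbons + 1

    @property
    def h_count_fame(self) -> int:
        """Hydrogen atoms in the straight-chain methyl ester.

        The free acid CH3-(chain)-COOH has ``2c - 2d`` H of which one is
        the exchangeable carboxyl H; esterification replaces it with a
        CH3 group, giving ``2c - 1 - 2d + 3 = 2c - 2d + 2``.
        """
        return 2 * self.carbons - 2 * self.double_bonds + 2

    @property
    def shorthand(self) -> str:
        """``"C:D"`` or ``"C:Dn-x"`` form, independent of trivial name."""
        if self.omega_class in ("n-3", "n-6", "n-9"):
            return f"{self.carbons}:{self.double_bonds}{self.omega_class}"
        return f"{self.carbons}:{self.double_bonds}"


# trivial name -> (carbons, double bonds, omega class)
_TRIVIAL = {
    "LIN": (18, 2, "n-6"),   # linoleic
    "ALA": (18, 3, "n-3"),   # alpha-linolenic
    "SDA": (18, 4, "n-3"),   # stearidonic
    "ARA": (20, 4, "n-6"),   # arachidonic
    "ETA": (20, 4, "n-3"),   # eicosatetraenoic
    "EPA": (20, 5, "n-3"),   # eicosapentaenoic
    "DPA": (22, 5, "n-3"),   # docosapentaenoic
    "DHA": (22, 6, "n-3"),   # docosahexaenoic
}

_SHORTHAND_RE = re.compile(r"^(\d{1,2}):(\d{1,2})(?:n-(\d{1,2}))?$")


class FattyAcidRegistry:
    """Mutable registry mapping trivial names to structures.

    The default registry carries the common trivial names above. "HTA",
    a brain-quantified fatty acid whose structure is not standardised,
    is registered as a *placeholder*: it parses (so brain feature tables
    can be built) but refuses to report FAME atom counts until the user
    registers an explicit structure for it.
    """

    PLACEHOLDER_NAMES = frozenset({"HTA"})

    def __init__(self) -> None:
        self._names: dict[str, FattyAcid] = {}
        for name, (c, d, om) in _TRIVIAL.items():
            self._names[name] = FattyAcid(name, c, d, om)

    def register(self, code: str, carbons: int, double_bonds: int,
                 omega_class: str = "other") -> FattyAcid:
        fa = FattyAcid(code, carbons, double_bonds, omega_class)
        self._names[code] = fa
        return fa

    @property
    def trivial_names(self) -> list[str]:
        return sorted(self._names) + sorted(
            self.PLACEHOLDER_NAMES - set(self._names))

    def parse(self, code: str) -> FattyAcid:
        """Parse a shorthand or trivial name into a :class:`FattyAcid`.

        Raises
        ------
        ValueError
            Unknown trivial name (message lists registered names) or
            malformed shorthand.
        """
        code = code.strip()
        if code in self._names:
            return self._names[code]
        if code in self.PLACEHOLDER_NAMES:
            return _PlaceholderFattyAcid(code)
        m = _SHORTHAND_RE.match(code)
        if m is None:
            raise ValueError(
                f"unknown fatty acid {code!r}: not C:D / C:Dn-x shorthand and "
                f"not a registered trivial name ({', '.join(self.trivial_names)})"
            )
        carbons, dbonds = int(m.group(1)), int(m.group(2))
        if m.group(3) is not None:
            omega = f"n-{m.group(3)}"
            if omega not in ("n-3", "n-6", "n-9"):
                omega_class = "other"
            else:
                omega_class = omega
            fa = FattyAcid(code, carbons, dbonds, omega_class)
        else:
            omega_class = "saturated" if dbonds == 0 else "other"
            fa = FattyAcid(code, carbons, dbonds, omega_class)
        return fa


class _PlaceholderFattyAcid(FattyAcid):
    """Identity-only fatty acid: usable as a feature label, not correctable."""

    def __init__(self, code: str) -> None:
        object.__setattr__(self, "code", code)
        object.__setattr__(self, "carbons", 0)
        object.__setattr__(self, "double_bonds", 0)
        object.__setattr__(self, "omega_class", "other")

    def __post_init__(self) -> None:  # pragma: no cover - never called
        pass

    @property
    def c_count_fame(self) -> int:
        raise ValueError(
            f"{self.code}: structure not registered; register an explicit "
            "structure before methylation correction")

    @property
    def h_count_fame(self) -> int:
        raise ValueError(
            f"{self.code}: structure not registered; register an explicit "
            "structure before methylation correction")

    @property
    def shorthand(self) -> str:
        return self.code


DEFAULT_REGISTRY = FattyAcidRegistry()


def parse_fa_name(code: str, registry: FattyAcidRegistry | None = None) -> FattyAcid:
    """Parse a fatty-acid name against *registry* (default registry if None)."""
    return (registry or DEFAULT_REGISTRY).parse(code)


#: The 11-FA panel measured in every sample of all four tissues.
CORE_PANEL = ("14:0", "16:0", "16:1", "18:0", "18:1",
              "LIN", "ALA", "ARA", "EPA", "DPA", "DHA")

#: Brain samples additionally carry HTA.
BRAIN_PANEL = CORE_PANEL + ("HTA",)
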