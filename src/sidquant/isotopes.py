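"""Chlorine isotopologue patterns and SIM channel derivation.

Chlorine has two stable isotopes, 35Cl (75.76%) and 37Cl (24.24%), roughly
the familiar "3:1" of mass spectrometry. A molecule with *n* chlorines
therefore shows an isotopologue envelope at M, M+2, ..., M+2n whose
proportions follow a binomial distribution in the number of 37Cl atoms.
For a di-chlorinated analyte such as dicamba the M:M+2 ratio is
0.7576^2 / (2 * 0.7576 * 0.2424) ~ 1.56, the "3:2" pattern used for
positive identification of chlorinated compounds.

On a unit-resolution quadrupole the monitored SIM channels are nominal
integer m/z: the 35Cl-only precursor and fragment ions carry most of the
signal and serve as quantification channels, while their +2 isotopologues
are optional confirmation channels. A deuterated internal standard shifts
every channel by its label mass (D3 -> +3 Da).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

CL35_ABUNDANCE = 0.7576
CL37_ABUNDANCE = 0.2424

__all__ = [
    "CL35_ABUNDANCE",
    "CL37_ABUNDANCE",
    "IsotopeDistribution",
    "CompoundIonSpec",
    "chlorine_pattern",
    "derive_sim_channels",
    "DICAMBA",
    "D3_DICAMBA",
]


@dataclass(frozen=True)
class IsotopeDistribution:
    """Chlorine isotopologue envelope of a molecule.

    ``fractions`` is an ordered tuple of ``(mass_offset, probability)``
    pairs with even offsets 0, 2, ..., 2*n_chlorines.
    """

    n_chlorines: int
    fractions: tuple[tuple[int, float], ...]

    def probability(self, mass_offset: int) -> float:
        """Probability of the isotopologue at the given mass offset (Da)."""
        for offset, p in self.fractions:
            if offset == mass_offset:
                return p
        raise KeyError(f"no isotopologue at mass offset {mass_offset}")

    @property
    def m_mplus2_ratio(self) -> float:
        """Ratio of the monoisotopic (all-35Cl) to the M+2 isotopologue."""
        if self.n_chlorines < 1:
            raise ValueError("M:M+2 ratio undefined without chlorine")
        return self.probability(0) / self.probability(2)


def chlorine_pattern(n_chlorines: int) -> IsotopeDistribution:
    """Binomial isotopologue distribution for ``n_chlorines`` chlorine atoms.

    The isotopologue with k 37Cl atoms sits at mass offset 2k with
    probability C(n, k) * a35^(n-k) * a37^k. For n = 0 the distribution is
    degenerate at offset 0.
    """
    if not isinstance(n_chlorines, (int,)) or isinstance(n_chlorines, bool):
        raise ValueError("n_chlorines must be an integer")
    if n_chlorines < 0:
        raise ValueError("n_chlorines must be non-negative")
    fractions = tuple(
        (
            2 * k,
            comb(n_chlorines, k)
            * CL35_ABUNDANCE ** (n_chlorines - k)
            * CL37_ABUNDANCE**k,
        )
        for k in range(n_chlorines + 1)
    )
    return IsotopeDistribution(n_chlorines=n_chlorines, fractions=fractions)


@dataclass(frozen=True)
class CompoundIonSpec:
    """SIM channel set for one compound (analyte or labeled standard).

    Quantification channels are the 35Cl-only precursor and fragment ions;
    confirmation channels are their +2 isotopologues. ``label_shift`` is
    the isotope-label mass offset applied to every channel (0 for the
    analyte, 3 for a D3 internal standard, assumed isotopically pure).
    """

    name: str
    precursor_mz: float
    fragment_mz: float
    n_chlorines: int
    label_shift: int = 0
    quant_channels: frozenset[float] = field(init=False)
    confirm_channels: frozenset[float] = field(init=False)

    def __post_init__(self) -> None:
        if self.fragment_mz <= 0 or self.precursor_mz <= 0:
            raise ValueError("m/z values must be positive")
        if self.fragment_mz >= self.precursor_mz:
            raise ValueError(
                f"fragment m/z ({self.fragment_mz}) must be below precursor "
                f"m/z ({self.precursor_mz})"
            )
        if self.n_chlorines < 0:
            raise ValueError("n_chlorines must be non-negative")
        if self.label_shift < 0:
            raise ValueError("label_shift must be non-negative")
        shift = self.label_shift
        object.__setattr__(
            self,
            "quant_channels",
            frozenset({self.fragment_mz + shift, self.precursor_mz + shift}),
        )
        object.__setattr__(
            self,
            "confirm_channels",
            frozenset(
                {self.fragment_mz + 2 + shift, self.precursor_mz + 2 + shift}
            ),
        )

    @property
    def isotope_pattern(self) -> IsotopeDistribution:
        return chlorine_pattern(self.n_chlorines)

    def all_channels(self, include_confirm: bool = True) -> frozenset[float]:
        if include_confirm:
            return self.quant_channels | self.confirm_channels
        return self.quant_channels


def derive_sim_channels(
    precursor_mz: float,
    fragment_mz: float,
    n_chlorines: int,
    label_shift: int = 0,
    name: str = "compound",
) -> CompoundIonSpec:
    """Build a :class:`CompoundIonSpec` from precursor/fragment ions.

    The label shift moves every channel, so an internal standard spec is
    simply the analyte spec with a nonzero shift (label-equivariance).
    """
    return CompoundIonSpec(
        name=name,
        precursor_mz=precursor_mz,
        fragment_mz=fragment_mz,
        n_chlorines=n_chlorines,
        label_shift=label_shift,
    )


#: Dicamba, [M-H]- m/z 219 with in-source decarboxylation fragment m/z 175.
DICAMBA = derive_sim_channels(219, 175, 2, 0, name="dicamba")

#: D3-dicamba internal standard: every dicamba channel shifted by +3 Da.
D3_DICAMBA = derive_sim_channels(219, 175, 2, 3, name="d3-dicamba")
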