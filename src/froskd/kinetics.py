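"""Closed-form kinetic and competition models for the apparent Kd.

Two mechanisms raise the apparent dissociation constant of a DNA-binding
protein in vivo above its in-vitro value:

* **Active degradation.** For a single-site reaction with bound-complex
  turnover, d(theta)/dt = kon*C*(1-theta) - (koff + kdeg)*theta, the steady
  state is half-occupied at C = (koff + kdeg)/kon, i.e. degradation
  multiplies the equilibrium Kd = koff/kon by (1 + kdeg/koff).

* **Non-specific genomic DNA.** With a specific constant Kd_s and a
  non-specific constant Kd_n, competition by genomic DNA at concentration
  [gDNA] gives an apparent Kd = Kd_s * (1 + [gDNA]/Kd_n); since
  Kd_n = Kd_s / ratio with ratio = Kd_s/Kd_n, the excess is exactly
  ratio * [gDNA] — a floor no operator engineering can beat.

Units: concentrations in nM, rates in s^-1, association rates in
nM^-1 s^-1 (1 nM^-1 s^-1 = 1e9 M^-1 s^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import AVOGADRO

__all__ = [
    "KineticRates",
    "CompetitionModel",
    "kdeg_from_halflife",
    "apparent_kd_with_degradation",
    "degradation_fold",
    "kd_from_rates",
    "koff_from_dwell",
    "koff_from_equilibrium",
    "kon_per_nM_s",
    "kon_per_M_s",
    "gdna_concentration",
    "apparent_kd_competition",
    "specific_from_apparent",
]


@dataclass
class KineticRates:
    """Binding (kon), dissociation (koff) and degradation (kdeg) rates.

    ``kon`` is in nM^-1 s^-1, the others in s^-1; ``kdeg = 0`` describes a
    stable protein.
    """

    kon: float
    koff: float
    kdeg: float = 0.0

    def __post_init__(self):
        if self.kon <= 0:
            raise ValueError("kon must be strictly positive")
        if self.koff < 0 or self.kdeg < 0:
            raise ValueError("koff and kdeg must be non-negative")


@dataclass
class CompetitionModel:
    """Specific vs non-specific DNA competition for a binding protein.

    ``kd_s`` (nM) is the specific-site dissociation constant, ``kd_ratio``
    the dimensionless ratio Kd_s/Kd_n (< 1: specific binding is tighter),
    and ``gdna`` (nM) the concentration of competitive genomic-DNA sites.
    """

    kd_s: float
    kd_ratio: float
    gdna: float

    def __post_init__(self):
        if not 0 < self.kd_ratio < 1:
            raise ValueError("kd_ratio must lie in (0, 1)")
        if self.kd_s <= 0 or self.gdna < 0:
            raise ValueError("kd_s must be positive and gdna non-negative")

    @property
    def kd_n(self) -> float:
        """Non-specific dissociation constant, nM."""
        return self.kd_s / self.kd_ratio

    def nonspecific_bound_fraction(self, free_total: float = 1.0) -> float:
        """Fraction of the diffusive-plus-nonspecific pool that is DNA-bound.

        With fast non-specific exchange, [TF.gDNA]/[TF] = gdna/Kd_n, so of a
        measured total free pool [TF]' = [TF] + [TF.gDNA] the DNA-associated
        share is gdna/(Kd_n + gdna), independent of ``free_total``.
        """
        del free_total
        return self.gdna / (self.kd_n + self.gdna)


def kdeg_from_halflife(t_half: float) -> float:
    """Degradation rate ln(2)/t_half, s^-1 (t_half in seconds)."""
    if t_half <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / t_half


def apparent_kd_with_degradation(rates: KineticRates) -> float:
    """Half-occupancy concentration (nM) of the degradation-coupled reaction.

    Steady state of d(theta)/dt = kon*C*(1-theta) - (koff+kdeg)*theta is
    theta = kon*C / (kon*C + koff + kdeg); theta = 1/2 at
    C = (koff + kdeg)/kon.
    """
    return (rates.koff + rates.kdeg) / rates.kon


def degradation_fold(koff: float, kdeg: float) -> float:
    """Fold increase of the apparent Kd over the equilibrium Kd: 1 + kdeg/koff."""
    if koff <= 0:
        raise ValueError("koff must be strictly positive")
    if kdeg < 0:
        raise ValueError("kdeg must be non-negative")
    return 1.0 + kdeg / koff


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant koff/kon, nM (kon in nM^-1 s^-1)."""
    if kon <= 0:
        raise ValueError("kon must be strictly positive")
    return koff / kon


def koff_from_dwell(t_off: float) -> float:
    """Dissociation rate from the mean bound dwell time: 1/t_off, s^-1."""
    if t_off <= 0:
        raise ValueError("dwell time must be positive")
    return 1.0 / t_off


def koff_from_equilibrium(kon: float, kd: float) -> float:
    """Dissociation rate implied by an equilibrium Kd: koff = kon * Kd (s^-1)."""
    if kon <= 0 or kd <= 0:
        raise ValueError("kon and kd must be positive")
    return kon * kd


def kon_per_nM_s(kon_per_m_s: float) -> float:
    """Convert an association rate from M^-1 s^-1 to nM^-1 s^-1."""
    return kon_per_m_s * 1e-9


def kon_per_M_s(kon_per_nm_s: float) -> float:
    """Convert an association rate from nM^-1 s^-1 to M^-1 s^-1."""
    return kon_per_nm_s * 1e9


def gdna_concentration(
    genome_bp: float = 12.1e6,
    competitive_fraction: float = 0.5,
    nuclear_volume_um3: float = 3.0,
) -> float:
    """Concentration (nM) of competitive genomic-DNA sites in the nucleus.

    Counts each base pair of the competitive fraction of the genome as one
    non-specific site confined to the nuclear volume.  The defaults (12.1 Mbp
    haploid genome, half of it competitive, 3.0 um^3 nucleus) give ~3.3 mM.
    """
    if genome_bp <= 0 or nuclear_volume_um3 <= 0:
        raise ValueError("genome size and nuclear volume must be positive")
    if not 0.0 <= competitive_fraction <= 1.0:
        raise ValueError("competitive_fraction must lie in [0, 1]")
    sites = genome_bp * competitive_fraction
    molar = sites / (AVOGADRO * nuclear_volume_um3 * 1e-15)   # mol/L
    return molar * 1e9


def apparent_kd_competition(model: CompetitionModel) -> float:
    """Apparent Kd (nM) under non-specific competition.

    Kd_apparent = Kd_s * (1 + gdna/Kd_n) = Kd_s + ratio * gdna exactly.
    """
    return model.kd_s * (1.0 + model.gdna / model.kd_n)


def specific_from_apparent(kd_apparent: float, kd_ratio: float, gdna: float) -> float:
    """Invert the competition relation: Kd_s = Kd_apparent - ratio * gdna."""
    kd_s = kd_apparent - kd_ratio * gdna
    if kd_s <= 0:
        raise ValueError(
            f"apparent Kd {kd_apparent:.4g} nM is below the competition floor "
            f"{kd_ratio * gdna:.4g} nM"
        )
    return kd_s
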