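"""Genotype state space, Mendelian transmission, founder priors.

Single autosomal diallelic locus: A is the wild allele, B the mutated
one. Genotype states are reported in the fixed order (AA, AB, BB).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError

__all__ = [
    "GENOTYPES",
    "GenotypeDist",
    "gamete_prob",
    "transmission",
    "hwe_prior",
    "uniform_prior",
    "fixed_prior",
]

#: The three diallelic genotype states, in canonical reporting order.
GENOTYPES = ("AA", "AB", "BB")

_B_DOSAGE = {"AA": 0, "AB": 1, "BB": 2}


def _check_genotype(g: str) -> str:
    if g not in GENOTYPES:
        raise ValidationError(f"unknown genotype {g!r}; expected one of {GENOTYPES}")
    return g


@dataclass(frozen=True)
class GenotypeDist:
    """Probability distribution over (AA, AB, BB)."""

    pAA: float
    pAB: float
    pBB: float

    def __post_init__(self) -> None:
        probs = (self.pAA, self.pAB, self.pBB)
        if any(p < 0.0 or p > 1.0 for p in probs):
            raise ValidationError(f"genotype probabilities outside [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValidationError(f"genotype probabilities must sum to 1: {probs}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pAA, self.pAB, self.pBB)

    def __getitem__(self, genotype: str) -> float:
        return self.as_tuple()[GENOTYPES.index(_check_genotype(genotype))]

    def b_dosage(self) -> float:
        """Expected number of B alleles."""
        return self.pAB + 2.0 * self.pBB


def gamete_prob(g: str) -> float:
    """Probability that a parent of genotype ``g`` transmits the B allele."""
    return _B_DOSAGE[_check_genotype(g)] / 2.0


def transmission(g_sire: str, g_dam: str) -> GenotypeDist:
    """Offspring genotype distribution under Mendelian segregation."""
    b_s = gamete_prob(g_sire)
    b_d = gamete_prob(g_dam)
    p_bb = b_s * b_d
    p_aa = (1.0 - b_s) * (1.0 - b_d)
    return GenotypeDist(pAA=p_aa, pAB=1.0 - p_aa - p_bb, pBB=p_bb)


def hwe_prior(q: float) -> GenotypeDist:
    """Founder genotype prior under Hardy-Weinberg equilibrium.

    ``q`` is the population frequency of the mutant allele B.
    """
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"allele frequency must be in [0, 1], got {q}")
    return GenotypeDist(pAA=(1.0 - q) ** 2, pAB=2.0 * q * (1.0 - q), pBB=q * q)


def uniform_prior() -> GenotypeDist:
    """Uninformed founder prior: 1/3 on each genotype."""
    third = 1.0 / 3.0
    return GenotypeDist(third, third, 1.0 - 2.0 * third)


def fixed_prior(genotype: str) -> GenotypeDist:
    """Point-mass founder prior on a known genotype."""
    _check_genotype(genotype)
    return GenotypeDist(*(1.0 if g == genotype else 0.0 for g in GENOTYPES))
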