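"""Zygotic X elimination: from zygote plus oocyte payload to adult fate.

Two-factor model: the elimination locus ``r`` supplies a fixed load of
two product doses whenever it is functional in the zygote ("its
quantity is similar in all embryos"); the oocyte's inhibitor doses
cancel it one-for-one (``[e]``) or one-for-two (``[e*]``).  Each
uncancelled dose removes one unprotected X chromosome.

One-factor model: the maternal product attacks the X directly, one
dose per chromosome; there is no ``r`` locus.

Imprinting protects every maternally contributed X.  Zygotes stripped
of all X chromosomes die; one surviving X makes a male (the retained
X's parental origin is recorded), two make a female.  Autosomal
alleles are never removed.  Excess doses are harmless.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Optional

from .model import (
    MATERNAL,
    PATERNAL,
    TWO_FACTOR,
    X_LINKED,
    Genotype,
    ModelConfig,
    ModelError,
    Number,
    female,
    male,
)
from .gametes import Zygote

HALF = Fraction(1, 2)

# fate masses are keyed by surviving (maternal_x, paternal_x) counts
_XState = tuple[int, int]


@dataclass(frozen=True)
class OutcomeDistribution:
    """Mass split of one zygote over adult genotypes and death."""

    outcomes: tuple[tuple[Optional[Genotype], Number], ...]  # None = dead

    @property
    def total(self) -> Number:
        return sum(m for _, m in self.outcomes)

    def survivors(self):
        return tuple((g, m) for g, m in self.outcomes if g is not None)


def r_dose(zygote: Zygote, config: ModelConfig) -> int:
    """Elimination-factor load of a two-factor zygote: 2 if ``r`` is
    functional under its configured dominance, else 0."""
    if config.variant != TWO_FACTOR:
        raise ModelError("r_dose is defined for the two-factor model only")
    spec = config.locus("r")
    alleles = [
        a
        for a in (
            zygote.maternal_alleles[config.index("r")],
            zygote.paternal_alleles[config.index("r")],
        )
        if a is not None
    ]
    derived = set(spec.derived)
    if spec.dominance == "dominant":
        on = any(a in derived for a in alleles)
    else:
        on = len(alleles) > 0 and all(a in derived for a in alleles)
    return 2 if on else 0


def inactivation_capacity(zygote: Zygote) -> int:
    """Doses of elimination factor the oocyte payload can neutralise:
    one per ``[e]``, two per ``[e*]``."""
    return zygote.cytoplasm_e + 2 * zygote.cytoplasm_estar


def active_doses(zygote: Zygote, config: ModelConfig) -> int:
    if config.variant == TWO_FACTOR:
        return max(0, r_dose(zygote, config) - inactivation_capacity(zygote))
    if zygote.cytoplasm_estar:
        raise ModelError("the one-factor model has no enhanced inhibitor e*")
    return zygote.cytoplasm_e


def _eliminate(
    start: _XState, protected: bool, doses: int
) -> dict[_XState, Fraction]:
    """Remove up to ``doses`` unprotected X chromosomes, one per dose.

    When maternal and paternal X's are both unprotected and one must
    go, the mass splits in proportion to copy number (half/half for an
    ordinary XX zygote: nothing distinguishes the two targets).
    Protected maternal X's are never touched; doses with no remaining
    target are wasted harmlessly.
    """
    states: dict[_XState, Fraction] = {start: Fraction(1, 1)}
    for _ in range(doses):
        nxt: dict[_XState, Fraction] = {}
        for (m, p), mass in states.items():
            m_cand = 0 if protected else m
            total = m_cand + p
            if total == 0:
                nxt[(m, p)] = nxt.get((m, p), Fraction(0)) + mass
                continue
            if p:
                key = (m, p - 1)
                nxt[key] = nxt.get(key, Fraction(0)) + mass * Fraction(p, total)
            if m_cand:
                key = (m - 1, p)
                nxt[key] = nxt.get(key, Fraction(0)) + mass * Fraction(m_cand, total)
        states = nxt
    return states


@lru_cache(maxsize=None)
def resolve(zygote: Zygote, config: ModelConfig) -> OutcomeDistribution:
    """Mass split of a zygote over adult genotypes and death."""
    if zygote.total_x not in (0, 1, 2, 3):
        raise ModelError(f"unsupported X count {zygote.total_x}")
    if zygote.paternal_x == 2 and not config.sciara:
        raise ModelError("double-X sperm require the Sciara preset")
    doses = active_doses(zygote, config)
    fates = _eliminate(
        (zygote.maternal_x, zygote.paternal_x),
        zygote.maternal_x_protected,
        doses,
    )
    outcomes: dict[Optional[Genotype], Number] = {}
    for (m, p), mass in fates.items():
        adult = _adult(zygote, config, m, p)
        outcomes[adult] = outcomes.get(adult, 0) + mass
    return OutcomeDistribution(tuple(sorted(outcomes.items(), key=lambda kv: str(kv[0]))))


def _adult(
    zygote: Zygote, config: ModelConfig, m_x: int, p_x: int
) -> Optional[Genotype]:
    total = m_x + p_x
    if total == 0:
        return None  # nullo-X zygotes are inviable
    if total >= 3:
        raise ModelError(
            "three-X survivors are not a modelled adult class; "
            "they arise only from misconfigured double-X sperm"
        )
    if total == 2:
        pairs = []
        for i, spec in enumerate(config.loci):
            if spec.linkage == X_LINKED:
                if m_x and p_x:
                    pair = (zygote.maternal_alleles[i], zygote.paternal_alleles[i])
                else:  # two identical paternal X copies survived
                    pair = (zygote.paternal_alleles[i], zygote.paternal_alleles[i])
                pairs.append(pair)
            else:
                pairs.append((zygote.maternal_alleles[i], zygote.paternal_alleles[i]))
        return female(config, pairs)
    origin = MATERNAL if m_x == 1 else PATERNAL
    pairs = []
    for i, spec in enumerate(config.loci):
        if spec.linkage == X_LINKED:
            if origin == MATERNAL:
                pairs.append((zygote.maternal_alleles[i], None))
            else:
                pairs.append((None, zygote.paternal_alleles[i]))
        else:
            pairs.append((zygote.maternal_alleles[i], zygote.paternal_alleles[i]))
    return male(
        config,
        pairs,
        imprinted=zygote.maternal_x_protected,
        x_origin=origin,
    )
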