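"""Core genotype algebra: loci, alleles, parent-of-origin tracking.

The model follows a small set of control genes that turn an ancestral
digenic XX/X0 sex-determination system into a monogenic one driven by
zygotic elimination of the paternal X chromosome:

* ``e`` — maternal inhibitor.  Expressed in the mother during oogenesis;
  its product accumulates in the oocyte with a dose equal to the
  mother's count of derived alleles (``e`` or the enhanced ``e*``).
* ``s`` — aberrant spermatogenesis.  Maternally and paternally derived
  chromosome complements segregate intact instead of mixing.
* ``r`` — zygotic elimination factor that removes unprotected X
  chromosomes (two-factor model only).
* ``g`` — maternal imprinting.  Marks the egg-borne chromosomes so the
  maternal X is protected in the zygote and the maternal complement is
  the one a son transmits.
* ``c`` — chromatid non-disjunction in spermatogenesis (the *Sciara*
  extension): X-bearing sperm deliver two identical X copies.

Ancestral alleles are written in upper case (``E S R G C``), derived
ones in lower case, and every individual carries an ordered
(maternal, paternal) allele pair per locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence, Union

Number = Union[int, float, Fraction]

FEMALE = "female"
MALE = "male"
MATERNAL = "maternal"
PATERNAL = "paternal"

RECESSIVE = "recessive"
DOMINANT = "dominant"
DOSAGE = "dosage"

AUTOSOMAL = "autosomal"
X_LINKED = "X_linked"

TWO_FACTOR = "two_factor"
ONE_FACTOR = "one_factor"


class ModelError(ValueError):
    """Raised for ill-formed genotypes or configurations."""


@dataclass(frozen=True)
class LocusSpec:
    """One control locus: its alleles, dominance semantics and linkage.

    ``dominance`` governs the *functional* test (whether the derived
    product is made): ``dominant`` means one derived copy suffices,
    ``recessive`` requires homozygosity, and ``dosage`` (locus ``e``
    only) means each derived copy contributes one product dose.
    """

    name: str
    ancestral: str
    derived: tuple[str, ...]
    dominance: str = RECESSIVE
    linkage: str = AUTOSOMAL

    def __post_init__(self) -> None:
        if self.name == "e" and self.dominance != DOSAGE:
            raise ModelError("locus e accumulates per-allele product doses")
        if self.name != "e" and self.dominance == DOSAGE:
            raise ModelError(f"locus {self.name} cannot use dosage semantics")
        if self.linkage == X_LINKED and self.name != "e":
            raise ModelError("only locus e may ride on the X chromosome")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ancestral,) + self.derived


@dataclass(frozen=True)
class ModelConfig:
    """A model variant plus its loci, in genotype print order."""

    loci: tuple[LocusSpec, ...]
    variant: str = TWO_FACTOR
    sciara: bool = False
    # label for X chromosomes carrying each allele of the X-linked locus,
    # e.g. {"e": "InvXe"} marks the inversion-bearing X of Sciara.
    x_symbols: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.variant not in (TWO_FACTOR, ONE_FACTOR):
            raise ModelError(f"unknown model variant {self.variant!r}")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ModelError("duplicate locus names")
        if self.variant == ONE_FACTOR and "r" in names:
            raise ModelError("the one-factor model has no elimination locus r")
        if sum(l.linkage == X_LINKED for l in self.loci) > 1:
            raise ModelError("at most one X-linked locus")

    def locus(self, name: str) -> LocusSpec:
        for spec in self.loci:
            if spec.name == name:
                return spec
        raise ModelError(f"locus {name!r} not in configuration")

    def index(self, name: str) -> int:
        for i, spec in enumerate(self.loci):
            if spec.name == name:
                return i
        raise ModelError(f"locus {name!r} not in configuration")

    def has(self, name: str) -> bool:
        return any(l.name == name for l in self.loci)

    @property
    def x_locus(self) -> Optional[LocusSpec]:
        for spec in self.loci:
            if spec.linkage == X_LINKED:
                return spec
        return None

    def x_symbol(self, allele: Optional[str]) -> str:
        if allele is None:
            return "X"
        return dict(self.x_symbols).get(allele, "X")

    def allele_order(self, name: str) -> dict[str, int]:
        spec = self.locus(name)
        return {a: i for i, a in enumerate(spec.alleles)}


@dataclass(frozen=True)
class Genotype:
    """One adult: sex plus a per-locus ordered (maternal, paternal) pair.

    Males are hemizygous X0; their single X came from one parent
    (``x_origin``) and an X-linked locus holds ``None`` in the other
    slot.  ``imprinted`` records whether the individual's mother carried
    out the imprinting process — the ``g(...)`` prefix of the label
    notation — which matters only for a male's spermatogenesis.
    """

    sex: str
    alleles: tuple[tuple[Optional[str], Optional[str]], ...]
    imprinted: bool = False
    x_origin: str = MATERNAL

    def pair(self, config: ModelConfig, name: str) -> tuple[Optional[str], Optional[str]]:
        return self.alleles[config.index(name)]

    def present(self, config: ModelConfig, name: str) -> tuple[str, ...]:
        """Non-missing alleles at a locus."""
        return tuple(a for a in self.pair(config, name) if a is not None)

    def count(self, config: ModelConfig, name: str, allele: str) -> int:
        return sum(a == allele for a in self.pair(config, name))


def _canonical_female(
    config: ModelConfig,
    alleles: Sequence[tuple[Optional[str], Optional[str]]],
) -> tuple[tuple[Optional[str], Optional[str]], ...]:
    # Heterozygote order is phenotypically inert in females (oogenesis is
    # Mendelian), so pairs are stored ancestral-allele first.
    out = []
    for spec, pair in zip(config.loci, alleles):
        if None in pair:
            raise ModelError(f"female missing an allele at locus {spec.name}")
        order = config.allele_order(spec.name)
        out.append(tuple(sorted(pair, key=order.__getitem__)))
    return tuple(out)


def female(config: ModelConfig, alleles: Mapping[str, Sequence[str]] | Sequence) -> Genotype:
    """Build a canonical female genotype.

    ``alleles`` maps locus name to an (unordered) allele pair, or gives
    pairs positionally in configuration order.
    """
    if isinstance(alleles, Mapping):
        pairs = [tuple(alleles[l.name]) for l in config.loci]
    else:
        pairs = [tuple(p) for p in alleles]
    return Genotype(FEMALE, _canonical_female(config, pairs))


def male(
    config: ModelConfig,
    alleles: Mapping[str, Sequence[Optional[str]]] | Sequence,
    imprinted: bool = False,
    x_origin: str = MATERNAL,
) -> Genotype:
    """Build a male genotype from ordered (maternal, paternal) pairs."""
    if isinstance(alleles, Mapping):
        pairs = [tuple(alleles[l.name]) for l in config.loci]
    else:
        pairs = [tuple(p) for p in alleles]
    for spec, pair in zip(config.loci, pairs):
        if spec.linkage == X_LINKED:
            slot = 0 if x_origin == MATERNAL else 1
            if pair[slot] is None or pair[1 - slot] is not None:
                raise ModelError(
                    f"male X-linked locus {spec.name} must sit on the {x_origin} X"
                )
        elif None in pair:
            raise ModelError(f"male missing an autosomal allele at {spec.name}")
    return Genotype(MALE, tuple(pairs), imprinted=imprinted, x_origin=x_origin)


def functional(genotype: Genotype, config: ModelConfig, name: str) -> bool:
    """Does the derived product of a dominant/recessive locus act?"""
    spec = config.locus(name)
    if spec.dominance == DOSAGE:
        raise ModelError("dosage locus e has no on/off functional test")
    derived = set(spec.derived)
    present = genotype.present(config, name)
    if spec.dominance == DOMINANT:
        return any(a in derived for a in present)
    return len(present) > 0 and all(a in derived for a in present)


def maternal_doses(mother: Genotype, config: ModelConfig) -> tuple[int, int]:
    """Oocyte doses (plain ``[e]``, enhanced ``[e*]``) from the mother's
    e-locus genotype."""
    if not config.has("e"):
        return (0, 0)
    pair = mother.present(config, "e")
    return (sum(a == "e" for a in pair), sum(a == "e*" for a in pair))


@dataclass(frozen=True)
class SelectionEntry:
    """Viability advantage for one derived allele.

    ``dominance`` is the *fitness* dominance: a ``dominant`` advantage
    rewards any carrier, a ``recessive`` one only homozygotes (for a
    hemizygous male, his single allele decides).  Non-favoured
    genotypes pay the selection coefficient ``mu``.
    """

    locus: str
    allele: str
    dominance: str = RECESSIVE
    mu: Number = 0.1


@dataclass(frozen=True)
class SelectionRegime:
    entries: tuple[SelectionEntry, ...] = ()

    def fitness(self, genotype: Genotype, config: ModelConfig) -> Number:
        w: Number = 1
        for entry in self.entries:
            present = genotype.present(config, entry.locus)
            if entry.dominance == DOMINANT:
                favoured = entry.allele in present
            else:
                favoured = len(present) > 0 and all(a == entry.allele for a in present)
            if not favoured:
                w = w * (1 - entry.mu)
        return w


NEUTRAL = SelectionRegime()


def advantage(locus: str, allele: str, dominance: str, mu: Number = 0.1) -> SelectionRegime:
    """Convenience: a single-locus viability advantage."""
    return SelectionRegime((SelectionEntry(locus, allele, dominance, mu),))
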