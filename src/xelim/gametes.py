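"""Gametogenesis: conventional oogenesis and complement-wise spermatogenesis.

Oogenesis is ordinary Mendelian segregation; what makes it special is
the maternal effect: every oocyte of one female carries the same
cytoplasmic dose of the inhibitor product, set by the *mother's*
e-locus genotype, and an imprint mark iff the mother performs the
imprinting process (functional ``g``).

Spermatogenesis has three regimes:

1. ``s`` not functional — ordinary meiosis, X- and nullo-X sperm in
   equal parts, autosomal loci independent.
2. ``s`` functional in an imprinted male — only the maternally derived
   complement survives: a single sperm class carrying the male's
   maternal X together with all his maternally derived alleles.
3. ``s`` functional in an unimprinted male — the two parental
   complements segregate intact, half the sperm carrying each; there
   are no recombinant classes.

Under the *Sciara* preset a functional ``c`` makes every X-bearing
sperm deliver two identical copies of its X.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import product
from typing import Optional

from .model import (
    FEMALE,
    MALE,
    MATERNAL,
    PATERNAL,
    X_LINKED,
    Genotype,
    ModelConfig,
    ModelError,
    Number,
    functional,
    maternal_doses,
)

HALF = Fraction(1, 2)


@dataclass(frozen=True)
class EggClass:
    """An oocyte class: haplotype plus the maternal-effect payload."""

    haplotype: tuple[str, ...]  # one allele per locus (X-linked: the egg X's allele)
    cytoplasm_e: int
    cytoplasm_estar: int
    imprint_mark: bool
    probability: Number


@dataclass(frozen=True)
class SpermClass:
    """A sperm class: haplotype and X content (0, 1 or 2 identical X)."""

    haplotype: tuple[Optional[str], ...]  # X-linked entry is None for nullo-X sperm
    x_content: int
    probability: Number


@lru_cache(maxsize=None)
def oogenesis(mother: Genotype, config: ModelConfig) -> tuple[EggClass, ...]:
    if mother.sex != FEMALE:
        raise ModelError("oogenesis requires a female")
    cyt_e, cyt_estar = maternal_doses(mother, config)
    mark = config.has("g") and functional(mother, config, "g")

    # X-linked loci co-segregate with the chosen X; autosomes are free.
    x_indices = [i for i, l in enumerate(config.loci) if l.linkage == X_LINKED]
    auto_indices = [i for i, l in enumerate(config.loci) if l.linkage != X_LINKED]
    # each segregation decision is a slot index (0=maternal X, 1=paternal X)
    x_options = [(0,), (1,)] if x_indices else [()]
    out: dict[tuple[str, ...], Number] = {}
    for x_choice in x_options:
        auto_iters = []
        for i in auto_indices:
            a, b = mother.alleles[i]
            auto_iters.append((a,) if a == b else (a, b))
        for combo in product(*auto_iters):
            hap = [None] * len(config.loci)
            p: Number = Fraction(1, 1)
            if x_indices:
                p *= HALF
                for i in x_indices:
                    hap[i] = mother.alleles[i][x_choice[0]]
            it = iter(combo)
            for i, options in zip(auto_indices, auto_iters):
                allele = next(it)
                hap[i] = allele
                if len(options) == 2:
                    p *= HALF
            key = tuple(hap)
            out[key] = out.get(key, 0) + p
    return tuple(
        EggClass(hap, cyt_e, cyt_estar, mark, p) for hap, p in sorted(out.items())
    )


def _complement(father: Genotype, config: ModelConfig, side: str) -> SpermClass:
    """The intact parental complement a son transmits under aberrant
    spermatogenesis: that side's autosomal alleles, plus the X iff the
    retained X belongs to that side."""
    slot = 0 if side == MATERNAL else 1
    hap: list[Optional[str]] = []
    has_x = father.x_origin == side
    for spec, pair in zip(config.loci, father.alleles):
        if spec.linkage == X_LINKED:
            hap.append(pair[slot] if has_x else None)
        else:
            hap.append(pair[slot])
    x_content = _x_content(father, config) if has_x else 0
    return SpermClass(tuple(hap), x_content, Fraction(1, 1))


def _x_content(father: Genotype, config: ModelConfig) -> int:
    if config.has("c") and functional(father, config, "c"):
        return 2
    return 1


@lru_cache(maxsize=None)
def spermatogenesis(father: Genotype, config: ModelConfig) -> tuple[SpermClass, ...]:
    if father.sex != MALE:
        raise ModelError("spermatogenesis requires a male")
    s_on = config.has("s") and functional(father, config, "s")
    if s_on and father.imprinted:
        return (_complement(father, config, MATERNAL),)
    if s_on:
        m = _complement(father, config, MATERNAL)
        p = _complement(father, config, PATERNAL)
        classes: dict[tuple, Number] = {}
        for c in (m, p):
            key = (c.haplotype, c.x_content)
            classes[key] = classes.get(key, 0) + HALF
        return tuple(SpermClass(h, x, pr) for (h, x), pr in sorted(classes.items(),
                     key=lambda kv: (kv[0][1], str(kv[0][0]))))

    # ordinary meiosis: X/0 half and half, autosomes independent
    x_slot = 0 if father.x_origin == MATERNAL else 1
    xc = _x_content(father, config)
    out: dict[tuple, Number] = {}
    auto_iters = []
    for spec, pair in zip(config.loci, father.alleles):
        if spec.linkage == X_LINKED:
            auto_iters.append(None)  # placeholder, filled per X choice
        else:
            a, b = pair
            auto_iters.append((a,) if a == b else (a, b))
    for bears_x in (True, False):
        base_p: Number = HALF
        iters = []
        for spec, options, pair in zip(config.loci, auto_iters, father.alleles):
            if options is None:
                iters.append((pair[x_slot] if bears_x else None,))
            else:
                iters.append(options)
        for combo in product(*iters):
            p = base_p
            for options in auto_iters:
                if options is not None and len(options) == 2:
                    p *= HALF
            key = (tuple(combo), xc if bears_x else 0)
            out[key] = out.get(key, 0) + p
    return tuple(
        SpermClass(h, x, pr)
        for (h, x), pr in sorted(out.items(), key=lambda kv: (kv[0][1], str(kv[0][0])))
    )


@dataclass(frozen=True)
class Zygote:
    """Maternal and paternal contributions plus the oocyte payload."""

    maternal_alleles: tuple[Optional[str], ...]
    paternal_alleles: tuple[Optional[str], ...]
    maternal_x: int
    paternal_x: int
    cytoplasm_e: int
    cytoplasm_estar: int
    maternal_x_protected: bool

    @property
    def total_x(self) -> int:
        return self.maternal_x + self.paternal_x


def fertilize(egg: EggClass, sperm: SpermClass) -> Zygote:
    return Zygote(
        maternal_alleles=egg.haplotype,
        paternal_alleles=sperm.haplotype,
        maternal_x=1,
        paternal_x=sperm.x_content,
        cytoplasm_e=egg.cytoplasm_e,
        cytoplasm_estar=egg.cytoplasm_estar,
        maternal_x_protected=egg.imprint_mark,
    )
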