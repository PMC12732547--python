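"""Genotype labels in the standard notation of the sciarid literature.

Females print as ``XX Ee ss rr gg`` with the ancestral allele first
(heterozygote order is inert in females and aggregated on output);
males print their maternal allele first (``eE`` is a male whose e
came from his mother) and carry a ``g(...)`` wrapper iff they were
born of an imprinting mother: ``g(X0 eE ss rr gg)``.  With an
X-linked maternal-factor locus the X symbols themselves carry the
allele, e.g. ``InvXeX cc ss rr gg`` for the inversion-X female.

``parse_genotype`` is the exact inverse of ``format_genotype`` on
canonical labels.
"""

from __future__ import annotations

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
    female,
    male,
)


def _x_part(genotype: Genotype, config: ModelConfig) -> str:
    xl = config.x_locus
    if genotype.sex == FEMALE:
        if xl is None:
            return "XX"
        m, p = genotype.pair(config, xl.name)
        # convention puts the marked (derived) X first: InvXeX, not XInvXe
        order = config.allele_order(xl.name)
        m, p = sorted((m, p), key=lambda a: -order[a])
        return config.x_symbol(m) + config.x_symbol(p)
    # male: maternal slot first, "0" for the missing side
    if xl is None:
        return "X0" if genotype.x_origin == MATERNAL else "0X"
    m, p = genotype.pair(config, xl.name)
    if genotype.x_origin == MATERNAL:
        return config.x_symbol(m) + "0"
    return "0" + config.x_symbol(p)


def format_genotype(genotype: Genotype, config: ModelConfig) -> str:
    parts = [_x_part(genotype, config)]
    for spec in config.loci:
        if spec.linkage == X_LINKED:
            continue
        m, p = genotype.pair(config, spec.name)
        parts.append(f"{m}{p}")
    body = " ".join(parts)
    if genotype.sex == MALE and genotype.imprinted:
        return f"g({body})"
    return body


def _take(text: str, tokens: list[tuple[str, Optional[str]]]) -> tuple[Optional[str], str]:
    """Match the longest token prefix; returns (value, rest)."""
    for tok, value in sorted(tokens, key=lambda t: -len(t[0])):
        if text.startswith(tok):
            return value, text[len(tok):]
    raise ModelError(f"cannot parse {text!r}")


def _x_tokens(config: ModelConfig) -> list[tuple[str, Optional[str]]]:
    xl = config.x_locus
    if xl is None:
        return [("X", "X"), ("0", None)]
    toks: list[tuple[str, Optional[str]]] = [("0", None)]
    for allele in xl.alleles:
        toks.append((config.x_symbol(allele), allele))
    return toks


def parse_genotype(label: str, config: ModelConfig) -> Genotype:
    text = label.strip()
    imprinted = False
    if text.startswith("g(") and text.endswith(")"):
        imprinted = True
        text = text[2:-1]
    parts = text.split()
    xl = config.x_locus
    x1, rest = _take(parts[0], _x_tokens(config))
    x2, rest = _take(rest, _x_tokens(config))
    if rest:
        raise ModelError(f"trailing X symbols in {label!r}")
    body = parts[1:]
    auto_loci = [l for l in config.loci if l.linkage != X_LINKED]
    if len(body) != len(auto_loci):
        raise ModelError(f"expected {len(auto_loci)} autosomal pairs in {label!r}")

    pairs: dict[str, tuple] = {}
    for spec, token in zip(auto_loci, body):
        toks = [(a, a) for a in spec.alleles]
        a, remainder = _take(token, toks)
        b, remainder = _take(remainder, toks)
        if remainder:
            raise ModelError(f"bad allele pair {token!r} at locus {spec.name}")
        pairs[spec.name] = (a, b)

    sex_female = x1 is not None and x2 is not None  # "0" parses to None
    if sex_female:
        if imprinted:
            raise ModelError("the g( ) wrapper applies to males only")
        if xl is not None:
            pairs[xl.name] = (x1, x2)
        ordered = [pairs[l.name] for l in config.loci]
        return female(config, ordered)

    x_origin = MATERNAL if x2 is None else PATERNAL
    if xl is not None:
        pairs[xl.name] = (x1, x2)
    ordered = [pairs[l.name] for l in config.loci]
    return male(config, ordered, imprinted=imprinted, x_origin=x_origin)


def format_state(state, config: ModelConfig, precision: int = 4) -> str:
    """A readable two-column summary of a population state."""
    lines = [f"generation {state.generation}   SR = {float(state.sex_ratio):.{precision}g}"]
    for title, table in (("females", state.females), ("males", state.males)):
        lines.append(title + ":")
        for g, f in sorted(table.items(), key=lambda kv: -float(kv[1])):
            lines.append(f"  {format_genotype(g, config):<32s} {float(f):.{precision}f}")
    return "\n".join(lines)
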