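"""Single-pair brood tables of the monogenic population, in exact
rational arithmetic, including the Sciara system where sperm carry two
identical X copies and zygotes start with three X chromosomes.
"""

from xelim import (
    cross,
    format_genotype,
    parse_genotype,
    sciara_two_factor_config,
    two_factor_config,
)


def show(mother, father, config):
    m = parse_genotype(mother, config)
    f = parse_genotype(father, config)
    print(f"{mother}  x  {father}")
    for adult, mass in sorted(cross(m, f, config).items(), key=lambda kv: -kv[1]):
        label = "dead" if adult is None else format_genotype(adult, config)
        print(f"    {label:32s} {mass}")
    print()


config = two_factor_config()
print("-- monogenic population, two-factor model --")
show("XX ee ss rr gg", "g(X0 EE ss rr gg)", config)   # -> androgenic daughters
show("XX ee ss rr gg", "g(X0 eE ss rr gg)", config)   # -> gynogenic daughters
show("XX Ee ss rr gg", "g(X0 EE ss rr gg)", config)   # -> sons only

sciara = sciara_two_factor_config()
print("-- Sciara: double-X sperm, triple-X zygotes --")
show("InvXeX cc ss rr gg", "g(X0 cc ss rr gg)", sciara)  # one paternal X removed
show("XX cc ss rr gg", "g(X0 cc ss rr gg)", sciara)      # both removed: sons

print(
    "Gynogenic mothers load two inhibitor doses into every oocyte, so no"
    "\nX is eliminated; androgenic mothers leave eliminator doses free and"
    "\nevery zygote loses its paternal X (or both, in Sciara) to become male."
)
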