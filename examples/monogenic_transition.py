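"""A complete digenic-to-monogenic transition, gene by gene.

Runs the (s r e) emergence sequence under recessive conditions with
imprinting fixed: aberrant spermatogenesis, then the eliminator, then
the maternal inhibitor.  The final population holds two female
castes — androgenic Ee mothers whose single inhibitor dose leaves one
eliminator dose free to delete the paternal X (all sons), and
gynogenic ee mothers whose double dose protects every zygote (all
daughters) — at one half each, with four male classes at one quarter.
"""

from xelim import find_scenario, format_state, run_scenario

result = run_scenario(find_scenario("s-rec/r-rec (s r e)"))

for stage in result.stages:
    print(
        f"after {stage.stage.locus}-emergence: {stage.outcome} "
        f"(generation {stage.trajectory.final.generation}, "
        f"introduced-allele frequency {stage.allele_frequency:.3f})"
    )

print(f"\nfinal outcome: {result.outcome}")
print(format_state(result.final, result.scenario.config))
print(
    "\nEe females are androgenic (all-son broods), ee females gynogenic"
    "\n(all-daughter broods); equal halves give a balanced sex ratio."
)
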