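"""The enhanced inhibitor allele e* (one dose neutralises two
eliminator doses) invading the established monogenic population.

With a dominant viability advantage the population stays monogenic but
its genotypic formula changes: Ee* females become the gynogenic caste
(their single e* dose protects every zygote), EE females the
androgenic caste, and a single male class g(X0 EE ss rr gg) remains.
"""

from xelim import enhanced_inhibitor_scenario, format_state, run_scenario

result = run_scenario(enhanced_inhibitor_scenario("dom"))
print(f"outcome: {result.outcome}")
print(format_state(result.final, result.scenario.config))
print(
    "\nFemales settle near (EE, Ee*) = (0.474, 0.526): the androgenic EE"
    "\nclass pays the 10% dominant-advantage penalty each generation."
)
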