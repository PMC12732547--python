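# xelim

Deterministic population genetics of the transition from **digenic** to
**monogenic** sex determination in insects with XX/X0 systems — the route
taken by sciarid fungus gnats, gall midges and springtails, where every
zygote starts with the same chromosome set and sex is decided afterwards
by elimination of the paternally inherited X chromosome.

The package is for evolutionary geneticists who want to simulate, probe
or extend this class of models: it implements the genotype/gamete
algebra, the zygotic X-elimination engine, the exact generation
recursion over an infinite panmictic population, and a catalogue of
gene-emergence scenarios, with single-pair crosses available in exact
rational arithmetic.

## The model

Four autosomal, unlinked control genes convert the ancestral XX/X0
system into a monogenic one:

* **s** — aberrant spermatogenesis: the maternally and paternally
  derived chromosome complements segregate intact, so a functional male
  transmits only his maternal, X-bearing complement (exclusive
  formation of X-bearing sperm).
* **r** — a zygotic elimination factor `[r]` that binds an unprotected
  X chromosome and removes it; its load is the same in every zygote
  (2 doses when functional).
* **e** — a maternal-effect inhibitor: the mother deposits one dose of
  `[e]` per derived allele she carries into every oocyte; each dose
  inactivates one dose of `[r]` (the enhanced allele `e*` inactivates
  two). In the one-factor variant `[e]` attacks the paternal X
  directly, one dose per chromosome.
* **g** — maternal imprinting: marks the egg-borne chromosomes so the
  maternal X cannot be touched in the zygote and the maternal
  complement is the one a son's spermatogenesis retains.

One generation is: oogenesis and spermatogenesis → random union of
gametes → zygotic elimination (`active = max(0, 2·[r functional] −
#[e] − 2·#[e*])` unprotected X's removed; 0 X = death, 1 X = male,
2 X = female) → viability selection `w(not favoured) = 1 − μ` with
μ = 0.1 → sex-ratio bookkeeping `SR = males/females` → per-sex
renormalisation. Everything is a deterministic mass computation; there
is no random number generator anywhere in the pipeline.

A population is **monogenic** when it holds both *gynogenic* females
(all-daughter broods; their oocytes carry two inhibitor doses, so no X
is eliminated) and *androgenic* females (all-son broods; one dose
leaves one eliminator dose free to delete the paternal X) and no female
with a mixed brood.

## Worked example

Introduce the eliminator allele *r* at frequency 0.05 (Hardy–Weinberg,
both sexes) into the imprinting-fixed ancestral population, with a
recessive 10 % viability advantage:

```python
from xelim import (advantage, ancestral_state, format_state,
                   introduce_allele, run_to_equilibrium, two_factor_config)

config = two_factor_config()
state = introduce_allele(ancestral_state(config), config, "r", "r", 0.05)
traj = run_to_equilibrium(state, advantage("r", "r", "recessive", 0.1), config)
print(format_state(traj.final, config))
```

prints

```
generation 608   SR = 1.222
females:
  XX EE SS RR gg                   0.5195
  XX EE SS Rr gg                   0.4805
males:
  g(X0 EE SS RR gg)                0.4250
  g(X0 EE SS Rr gg)                0.2587
  g(X0 EE SS rr gg)                0.1818
  g(X0 EE SS rR gg)                0.1344
```

Reading: *rr* zygotes from mothers without the inhibitor lose their
paternal X and develop as males, so no *rr* females exist, heterozygous
males come in both parental orders (`Rr` maternal-R vs `rR`
maternal-r), and the conversion of daughters into sons drives the sex
ratio to 1.22 males per female.

The `examples/` scripts walk through each capability — the
drive–selection equilibrium for *s*, a complete (s r e) transition to
the 0.5/0.5 monogenic state, exact brood tables (including the
*Sciara* double-X-sperm system), the enhanced inhibitor `e*`, and the
full emergence grid. A thin CLI mirrors them:

```bash
xelim presets                         # list catalogue scenarios
xelim run "s-rec/r-rec (s r e)" --out trajectory.tsv
xelim cross "XX ee ss rr gg" "g(X0 EE ss rr gg)"
xelim grid --out outcomes.tsv
```

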