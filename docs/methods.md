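# Methods

## Model and assumptions

`xelim` iterates an exact deterministic recursion over genotype
frequencies in an infinite panmictic population with discrete,
non-overlapping generations and no migration. The update order within a
generation is gametogenesis → random fertilisation → zygotic X
elimination → viability selection → sex-ratio bookkeeping → per-sex
renormalisation; the adult stage is the generational census. Mating is
neutral (all genotypes pair at random, equal fecundity) and males are
never limiting: a male class fertilises in proportion to its frequency
regardless of total male mass, reflecting sperm excess. Because the fate
of a zygote depends only on the egg class (which carries the
maternal-effect payload and the imprint mark) and the sperm class,
gametes are pooled over parents before fertilisation; this pooling is an
algebraic identity under random mating, not an approximation, and the
test suite checks it against an explicit per-pair expansion.

Genotypes track, per locus, the ordered (maternal, paternal) allele
pair. Female heterozygote order is phenotypically inert (oogenesis is
Mendelian) and is aggregated; male order matters because aberrant
spermatogenesis transmits the *maternal* complement, so `Ee` and `eE`
males are distinct classes. Males also record which parent contributed
their retained X and whether their mother performed imprinting (the
`g(...)` label wrapper) — the latter decides their spermatogenesis
regime, not their own genotype at g.

### Loci

| locus | product / action | functional test | default |
|-------|------------------|-----------------|---------|
| e | maternal inhibitor `[e]`; dose = mother's derived-allele count; 1 dose inactivates 1 `[r]` dose (`e*`: 2 doses); one-factor variant: deletes one paternal X per dose | dosage (per-allele) | — |
| s | complement-wise spermatogenesis | recessive or dominant per scenario | recessive |
| r | zygotic eliminator `[r]`; full 2-dose load whenever functional | recessive or dominant per scenario | recessive |
| g | maternal imprinting: protects the maternal X in the zygote and selects the maternal complement in sons' spermatogenesis | recessive | recessive |
| c | chromatid non-disjunction (*Sciara*): X-bearing sperm carry 2 identical X copies | recessive | recessive |

The eliminator load is all-or-nothing (2 doses when functional, 0
otherwise) rather than per-allele: the quantity of elimination factor is
taken to be the same in every embryo, and the worked crosses always pit
one or two inhibitor doses against the full load in homozygous zygotes.
Unused doses of either factor are harmless; elimination removes only X
chromosomes, never autosomal alleles. Zygotes stripped of every X die;
the single-removal split of an entirely unprotected XX zygote is an even
mass split (nothing distinguishes the two targets), a branch reachable
only in transient non-imprinting states.

### Selection

A selection regime assigns a derived allele a viability advantage with
its own fitness dominance: non-favoured genotypes (hemizygous males
judged on their single allele) are weighted by 1 − μ, with μ = 0.1
throughout. Selection acts identically on both sexes at the adult
stage. The sex ratio SR is recorded after selection and before
renormalisation; this placement reproduces the printed intermediate sex
ratios (e.g. 1/0.9 ≈ 1.11 for the eliminator-drive state, 0.62 for the
spermatogenesis drive balance) where the pre-selection alternative does
not.

## Scenario protocol

A scenario is an ordered list of gene-emergence stages on top of an
initial digenic population (imprinting fixed, ancestral-at-g, or
lacking the g locus entirely). Each stage seeds its allele by
independent per-copy replacement at frequency 0.05 — a deterministic
mass redistribution that lands exactly on Hardy–Weinberg and linkage
equilibrium (the 0.9025/0.095/0.0025 neutral state) — then iterates to
equilibrium and classifies the outcome before the next gene appears.

Three protocol choices matter and are deliberate:

* **Regimes carry forward.** A gene's viability advantage stays in
  force while later genes emerge. The printed intermediate states
  require this (the drive state following an established eliminator
  keeps SR = 1/0.9; the final state of the recessive-s/dominant-r grid
  retains the S/s drive polymorphism, which only an active s advantage
  maintains). The `Stage` API also supports per-stage-only regimes.
* **A neutral settling phase follows the last stage.** An emergence
  episode's advantage drives the invasion but need not persist once the
  gene is established; the canonical final states are the neutral
  equilibria. Settling turns the selected end state of a completed
  transition into the exact 0.5/0.5 monogenic composition with four
  equifrequent male classes and SR = 1 within a couple of generations.
  The enhanced-inhibitor preset, whose final state is *maintained* by
  ongoing selection, switches settling off.
* **Lost alleles are purged at stage boundaries.** Deterministic decay
  is asymptotic, so an eliminated allele leaves a float residue
  (10⁻⁸–10⁻¹⁵); a later stage that reverses the selective landscape
  could re-amplify it — for instance, once imprinting spreads through
  an aberrant-spermatogenesis population, a vanished S residue would
  resurge as the only source of sons and avert the extinction the
  model actually predicts. Alleles below the loss threshold are
  therefore removed outright between stages, matching the stage-wise
  accounting in which an eliminated gene is simply gone.

The emergence catalogue fixes, per sequence, the selection branch under
which each gene is analysed (e.g. the maternal inhibitor is neutral
when it precedes spermatogenesis in the successful (e s r) route, but
carries the recessive advantage — and sweeps to homozygosity, blocking
the transition — in the (e r s)/(r e s) orderings). These branch
choices are part of the catalogue definition; the grid's qualitative
conclusions (which orderings reach the monogenic state, which end in
extinction or allele loss) are computed, not asserted.

## Numerical choices

* Frequencies are plain Python dict arithmetic over the reachable
  genotype space (≤ a few hundred classes). All computations accept
  `fractions.Fraction` inputs: crosses, fixed-point checks and the
  Hardy–Weinberg seeding are exact; long equilibrium runs use floats.
* Convergence: L∞ change of the per-sex frequency vectors plus the sex
  ratio < 1e-10, capped at 20 000 generations. Non-convergence is
  reported on the trajectory, never raised.
* Extinction: a sex whose unrenormalised mass falls below 1e-9 in one
  generation. (Geometric male-mass decay under spreading imprinting
  reaches this quickly; the threshold only makes the limit decidable.)
* Presence threshold for classification: 1e-6. Allele-loss threshold:
  1e-4 — near-neutral decay is quadratic (power-law in time), so tiny
  residues outlive any generation cap, while established alleles sit at
  percent scale; 1e-4 separates the two decidably. For the same reason
  a brood counts as single-sex when its minority-sex fraction is below
  1e-3 (residue leakage sits at ≤ 1e-4, genuine mixed broods at
  ≥ 1e-2).
* Genotypes below 1e-15 are pruned (float runs only) to keep tables
  small; this is far below every decision threshold.

## What the scenario runs do and do not show

The recursion itself has no free parameters beyond the stated μ,
introduction frequency and thresholds; the scenario catalogue inherits
the idealisations of the underlying model — infinite population (no
drift, so a recessive rare allele can only establish through its
homozygote excess), no mutation beyond the scripted introductions, no
recombination map (all loci unlinked), no dosage compensation, and no
germline/soma distinction. Outcomes of real populations at finite size,
where drift can fix or lose alleles the deterministic flow merely
erodes, may differ — in particular the knife-edge branches where an
allele's fate here depends on whether its decay is first- or
second-order.

Two printed states are documented as *not* reproducible under the
stated rules and are exposed as trajectories rather than matched: the
one-factor intermediate in which a neutral maternal eliminator
allegedly persists at (0.625, 0.375) — in this recursion such an allele
makes all-male broods in a balanced population and declines — and the
small heterozygote-order asymmetries and sex ratios printed for the
selected final-state variants of the recessive/recessive grid. The
test suite covers these with fixed-point, conservation, oracle and
round-trip property checks instead.

## Limitations

* The *Sciara* presets model the inversion X only as a label on the
  X-linked inhibitor haplotype (recombination is absent anyway); germ
  line-limited chromosomes and soma/germline elimination differences
  are out of scope.
* Classification interrogates broods against the *current* male pool;
  a female class's gynogenic/androgenic character is contextual, as in
  the source material.
* Trajectories of slow near-neutral transits (power-law modes) end at
  the generation cap with the non-converged flag set; interpreting such
  a truncated state as an equilibrium is the caller's responsibility.
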