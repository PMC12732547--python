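"""Deterministic generation-to-generation recursion.

An infinite panmictic population with discrete, non-overlapping
generations: every (mother, father) pairing is weighted by the product
of the parents' frequencies, with equal fecundity and no limit on male
fertilisation.  Because mating is random and the zygote's fate depends
only on the egg class (which carries the maternal-effect payload) and
the sperm class, gametes can be pooled over parents before
fertilisation — the recursion is exact, not an approximation.

The update order within a generation is: gametogenesis, fertilisation,
zygotic X elimination, viability selection, sex-ratio bookkeeping,
per-sex renormalisation.  The sex ratio SR (males/females) is recorded
after selection and before renormalisation.  There is no randomness
anywhere: "random" elimination targets are deterministic mass splits,
so every trajectory is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .gametes import EggClass, SpermClass, fertilize, oogenesis, spermatogenesis
from .model import (
    FEMALE,
    MALE,
    Genotype,
    ModelConfig,
    ModelError,
    NEUTRAL,
    Number,
    SelectionRegime,
    female,
    male,
)
from .resolution import resolve

#: genotypes below this frequency are dropped (float runs only); well
#: under the allele-loss threshold, so classification is unaffected.
PRUNE_EPS = 1e-15
#: presence threshold for classification
PRESENCE_EPS = 1e-6
#: an introduced allele below this frequency counts as eliminated.
#: Near-neutral deterministic decay is a power law, so tiny residues
#: outlive any generation cap; established polymorphisms sit orders of
#: magnitude higher (percent scale), so 1e-4 separates them cleanly.
LOSS_EPS = 1e-4
#: a brood is single-sex when the minority sex falls below this
#: fraction (asymptotic residues of vanishing genotypes leak opposite-
#: sex offspring at <= 1e-4; genuinely mixed broods sit at >= 1e-2)
BROOD_EPS = 1e-3
#: a sex whose unrenormalised mass falls below this is treated as gone
EXTINCTION_EPS = 1e-9


class ExtinctionError(RuntimeError):
    """The population lost one sex entirely."""

    def __init__(self, cause: str):
        super().__init__(cause)
        self.cause = cause


FreqTable = dict[Genotype, Number]


@dataclass
class PopulationState:
    """Per-sex genotype frequency tables plus the adult sex ratio."""

    females: FreqTable
    males: FreqTable
    sex_ratio: Number = 1
    generation: int = 0

    def copy(self) -> "PopulationState":
        return PopulationState(
            dict(self.females), dict(self.males), self.sex_ratio, self.generation
        )

    def check(self, tol: float = 1e-9) -> None:
        for table in (self.females, self.males):
            total = sum(table.values())
            if abs(float(total) - 1.0) > tol or any(float(v) < -tol for v in table.values()):
                raise ModelError("frequency table is not a distribution")

    def to_float(self) -> "PopulationState":
        return PopulationState(
            {g: float(v) for g, v in self.females.items()},
            {g: float(v) for g, v in self.males.items()},
            float(self.sex_ratio),
            self.generation,
        )

    def allele_frequency(self, config: ModelConfig, locus: str, allele: str) -> float:
        """Highest per-sex frequency of an allele (copies over slots)."""
        freqs = []
        for table in (self.females, self.males):
            copies = 0.0
            slots = 0.0
            for g, f in table.items():
                present = g.present(config, locus)
                slots += float(f) * len(present)
                copies += float(f) * sum(a == allele for a in present)
            freqs.append(copies / slots if slots else 0.0)
        return max(freqs)


def egg_pool(state: PopulationState, config: ModelConfig) -> dict[EggClass, Number]:
    pool: dict[EggClass, Number] = {}
    for mother, freq in state.females.items():
        for egg in oogenesis(mother, config):
            key = EggClass(
                egg.haplotype, egg.cytoplasm_e, egg.cytoplasm_estar, egg.imprint_mark, 1
            )
            pool[key] = pool.get(key, 0) + freq * egg.probability
    return pool


def sperm_pool(state: PopulationState, config: ModelConfig) -> dict[SpermClass, Number]:
    pool: dict[SpermClass, Number] = {}
    for father, freq in state.males.items():
        for sperm in spermatogenesis(father, config):
            key = SpermClass(sperm.haplotype, sperm.x_content, 1)
            pool[key] = pool.get(key, 0) + freq * sperm.probability
    return pool


def next_generation(
    state: PopulationState,
    selection: SelectionRegime = NEUTRAL,
    config: ModelConfig = None,
) -> PopulationState:
    if config is None:
        raise ModelError("a ModelConfig is required")
    eggs = egg_pool(state, config)
    sperm = sperm_pool(state, config)

    females: FreqTable = {}
    males: FreqTable = {}
    for egg, emass in eggs.items():
        for sp, smass in sperm.items():
            mass = emass * smass
            if not mass:
                continue
            for adult, share in resolve(fertilize(egg, sp), config).survivors():
                table = females if adult.sex == FEMALE else males
                table[adult] = table.get(adult, 0) + mass * share

    # viability selection acts identically on both sexes at the adult stage
    for table in (females, males):
        for g in table:
            table[g] = table[g] * selection.fitness(g, config)

    female_mass = sum(females.values())
    male_mass = sum(males.values())
    if float(female_mass) <= EXTINCTION_EPS:
        raise ExtinctionError("no females")
    if float(male_mass) <= EXTINCTION_EPS:
        raise ExtinctionError("no males")
    sr = male_mass / female_mass

    females = {g: v / female_mass for g, v in females.items()}
    males = {g: v / male_mass for g, v in males.items()}
    if isinstance(female_mass, float):
        females = _prune(females)
        males = _prune(males)
    return PopulationState(females, males, sr, state.generation + 1)


def _prune(table: FreqTable) -> FreqTable:
    kept = {g: v for g, v in table.items() if v > PRUNE_EPS}
    total = sum(kept.values())
    return {g: v / total for g, v in kept.items()}


def introduce_allele(
    state: PopulationState,
    config: ModelConfig,
    locus: str,
    allele: str,
    freq: Number,
    source_allele: Optional[str] = None,
) -> PopulationState:
    """Seed a derived allele at linkage and Hardy–Weinberg equilibrium.

    Every copy of the source allele (the ancestral allele by default),
    in both sexes and both parental slots, is independently replaced by
    the new allele with probability ``freq`` — a deterministic mass
    redistribution, not a sampling step.
    """
    spec = config.locus(locus)
    if source_allele is None:
        source_allele = spec.ancestral
    if allele not in spec.alleles:
        raise ModelError(f"allele {allele!r} unknown at locus {locus}")
    if not (0 <= float(freq) <= 1):
        raise ModelError("introduction frequency must lie in [0, 1]")
    idx = config.index(locus)

    def redistribute(table: FreqTable, sex: str) -> FreqTable:
        out: FreqTable = {}
        for g, f in table.items():
            slots = [s for s in (0, 1) if g.alleles[idx][s] == source_allele]
            masses = {(): f}
            for s in slots:
                nxt = {}
                for chosen, m in masses.items():
                    nxt[chosen + (False,)] = nxt.get(chosen + (False,), 0) + m * (1 - freq)
                    nxt[chosen + (True,)] = nxt.get(chosen + (True,), 0) + m * freq
                masses = nxt
            for flags, m in masses.items():
                if not m:
                    continue
                pair = list(g.alleles[idx])
                for s, hit in zip(slots, flags):
                    if hit:
                        pair[s] = allele
                alleles = list(g.alleles)
                alleles[idx] = tuple(pair)
                if sex == FEMALE:
                    ng = female(config, alleles)
                else:
                    ng = male(config, alleles, imprinted=g.imprinted, x_origin=g.x_origin)
                out[ng] = out.get(ng, 0) + m
        return out

    return PopulationState(
        redistribute(state.females, FEMALE),
        redistribute(state.males, MALE),
        state.sex_ratio,
        state.generation,
    )


def purge_lost_alleles(
    state: PopulationState, config: ModelConfig, eps: float = LOSS_EPS
) -> PopulationState:
    """Remove genotypes carrying alleles that have dropped below the
    loss threshold, renormalising each sex.

    Deterministic decay is asymptotic, so an eliminated allele leaves a
    vanishing float residue; a later shift of the selective landscape
    could re-amplify such a residue, which has no counterpart in the
    stage-wise accounting where an eliminated gene is simply gone.
    Called at stage boundaries by the scenario runner."""
    lost: list[tuple[str, str]] = []
    for spec in config.loci:
        for allele in spec.alleles:
            freq = state.allele_frequency(config, spec.name, allele)
            if 0.0 < freq < eps:
                lost.append((spec.name, allele))
    if not lost:
        return state
    indices = [(config.index(name), allele) for name, allele in lost]

    def clean(table: FreqTable) -> FreqTable:
        kept = {
            g: f
            for g, f in table.items()
            if not any(allele in g.alleles[i] for i, allele in indices)
        }
        total = sum(kept.values())
        if not total:
            return dict(table)  # refuse to empty a sex
        return {g: f / total for g, f in kept.items()}

    return PopulationState(
        clean(state.females), clean(state.males), state.sex_ratio, state.generation
    )


@dataclass
class Trajectory:
    """A recursion run: visited states, convergence and extinction flags."""

    states: list[PopulationState]
    converged: bool
    delta: float
    extinct: Optional[str] = None  # cause, if the run lost one sex

    @property
    def final(self) -> PopulationState:
        return self.states[-1]

    @property
    def generations(self) -> int:
        return self.final.generation - self.states[0].generation


def _state_delta(a: PopulationState, b: PopulationState) -> float:
    delta = abs(float(a.sex_ratio) - float(b.sex_ratio))
    for ta, tb in ((a.females, b.females), (a.males, b.males)):
        for g in ta.keys() | tb.keys():
            delta = max(delta, abs(float(ta.get(g, 0)) - float(tb.get(g, 0))))
    return delta


def run_to_equilibrium(
    state: PopulationState,
    selection: SelectionRegime = NEUTRAL,
    config: ModelConfig = None,
    tol: float = 1e-10,
    max_gens: int = 20000,
    record_every: int = 1,
) -> Trajectory:
    """Iterate the recursion until the L-infinity change (including the
    sex ratio) drops below ``tol``.  Non-convergence is reported in the
    returned trajectory, not raised; extinction is recorded as a cause."""
    if tol <= 0:
        raise ModelError("tolerance must be positive")
    states = [state]
    current = state
    delta = float("inf")
    for step in range(1, max_gens + 1):
        try:
            nxt = next_generation(current, selection, config)
        except ExtinctionError as exc:
            return Trajectory(states, False, delta, extinct=exc.cause)
        delta = _state_delta(current, nxt)
        current = nxt
        if step % record_every == 0 or delta < tol:
            states.append(current)
        if delta < tol:
            return Trajectory(states, True, delta)
    if states[-1] is not current:
        states.append(current)
    return Trajectory(states, False, delta)


def brood_profile(
    mother: Genotype,
    male_pool: Mapping[Genotype, Number],
    config: ModelConfig,
) -> tuple[Number, Number, dict[Optional[Genotype], Number]]:
    """Resolve all offspring of one female against a frequency-weighted
    male pool; returns (daughter fraction, son fraction, distribution)
    over surviving offspring (the distribution also lists dead mass
    under ``None``)."""
    total_m = sum(male_pool.values())
    dist: dict[Optional[Genotype], Number] = {}
    for egg in oogenesis(mother, config):
        for father, ffreq in male_pool.items():
            for sp in spermatogenesis(father, config):
                mass = egg.probability * (ffreq / total_m) * sp.probability
                for adult, share in resolve(fertilize(egg, sp), config).outcomes:
                    dist[adult] = dist.get(adult, 0) + mass * share
    daughters = sum(m for g, m in dist.items() if g is not None and g.sex == FEMALE)
    sons = sum(m for g, m in dist.items() if g is not None and g.sex == MALE)
    live = daughters + sons
    if not live:
        return 0, 0, dist
    return daughters / live, sons / live, dist


DIGENIC = "digenic"
MONOGENIC = "monogenic"
MIXED = "mixed"
EXTINCT = "extinct"


def classify(
    state: PopulationState,
    config: ModelConfig,
    introduced: Optional[tuple[str, str]] = None,
) -> str:
    """Outcome class of a population state.

    *monogenic*: every female class above the presence threshold has a
    single-sex brood against the current male pool, and both a
    female-producing and a male-producing class are present.
    *digenic*: no female class has a single-sex brood.  *mixed*:
    anything in between.  With ``introduced=(locus, allele)`` the
    answer is ``allele_lost(locus)`` when that allele has dropped below
    the loss threshold.
    """
    if not state.males or not state.females:
        return EXTINCT
    if introduced is not None:
        locus, allele = introduced
        if state.allele_frequency(config, locus, allele) < LOSS_EPS:
            return f"allele_lost({locus})"
    single_sex = 0
    gynogenic = androgenic = False
    n_females = 0
    for mother, freq in state.females.items():
        if float(freq) <= PRESENCE_EPS:
            continue
        n_females += 1
        d, s, _ = brood_profile(mother, state.males, config)
        if float(s) <= BROOD_EPS:
            single_sex += 1
            gynogenic = True
        elif float(d) <= BROOD_EPS:
            single_sex += 1
            androgenic = True
    if single_sex == n_females and gynogenic and androgenic:
        return MONOGENIC
    if single_sex == 0:
        return DIGENIC
    return MIXED
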