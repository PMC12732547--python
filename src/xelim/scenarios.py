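"""Scenario definitions, the emergence-sequence catalogue, and crosses.

A scenario starts from a digenic XX/X0 population (with imprinting
fixed, absent, or segregating) and introduces derived alleles one
stage at a time: seed the allele at Hardy–Weinberg proportions, run
the recursion to equilibrium under the stage's selection regime, and
classify the outcome before the next stage begins.

The built-in catalogue covers the full grid of emergence sequences of
the maternal inhibitor (e), aberrant spermatogenesis (s) and the
eliminator (r) under every dominance combination for (s) and (r), the
same sequences without imprinting, the imprinting-acquisition
sequences where (g) itself must spread, the enhanced-inhibitor allele
(e*), and the one-factor model.  Each stage uses the selection regime
under which the corresponding analysis establishes (or fails to
establish) the allele; the regimes are part of the catalogue, not
fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .dynamics import (
    EXTINCT,
    PopulationState,
    Trajectory,
    classify,
    introduce_allele,
    purge_lost_alleles,
    run_to_equilibrium,
)
from .gametes import fertilize, oogenesis, spermatogenesis
from .model import (
    DOMINANT,
    DOSAGE,
    FEMALE,
    MALE,
    NEUTRAL,
    ONE_FACTOR,
    RECESSIVE,
    TWO_FACTOR,
    X_LINKED,
    Genotype,
    LocusSpec,
    ModelConfig,
    ModelError,
    Number,
    SelectionRegime,
    advantage,
    female,
    male,
)
from .resolution import resolve

DEFAULT_INTRO_FREQ = 0.05


# ---------------------------------------------------------------------------
# configurations and canonical starting states


def two_factor_config(s_dominance: str = RECESSIVE, r_dominance: str = RECESSIVE,
                      with_g: bool = True) -> ModelConfig:
    loci = [
        LocusSpec("e", "E", ("e", "e*"), DOSAGE),
        LocusSpec("s", "S", ("s",), s_dominance),
        LocusSpec("r", "R", ("r",), r_dominance),
    ]
    if with_g:
        loci.append(LocusSpec("g", "G", ("g",), RECESSIVE))
    return ModelConfig(tuple(loci), TWO_FACTOR)


def one_factor_config() -> ModelConfig:
    return ModelConfig(
        (
            LocusSpec("e", "E", ("e",), DOSAGE),
            LocusSpec("s", "S", ("s",), RECESSIVE),
            LocusSpec("g", "G", ("g",), RECESSIVE),
        ),
        ONE_FACTOR,
    )


def sciara_two_factor_config() -> ModelConfig:
    """The Sciara preset: e rides on the X (the inversion-bearing X'
    carries the derived allele), plus the chromatid-non-disjunction
    locus c; X-bearing sperm deliver two identical X copies."""
    return ModelConfig(
        (
            LocusSpec("e", "E", ("e",), DOSAGE, X_LINKED),
            LocusSpec("c", "C", ("c",), RECESSIVE),
            LocusSpec("s", "S", ("s",), RECESSIVE),
            LocusSpec("r", "R", ("r",), RECESSIVE),
            LocusSpec("g", "G", ("g",), RECESSIVE),
        ),
        TWO_FACTOR,
        sciara=True,
        x_symbols=(("e", "InvXe"),),
    )


def sciara_one_factor_config() -> ModelConfig:
    """One-factor Sciara: every ordinary X carries the maternal-factor
    allele; the inversion X is the one lacking it."""
    return ModelConfig(
        (
            LocusSpec("e", "E", ("e",), DOSAGE, X_LINKED),
            LocusSpec("c", "C", ("c",), RECESSIVE),
            LocusSpec("s", "S", ("s",), RECESSIVE),
            LocusSpec("g", "G", ("g",), RECESSIVE),
        ),
        ONE_FACTOR,
        sciara=True,
        x_symbols=(("e", "Xe"), ("E", "InvX")),
    )


def ancestral_state(
    config: ModelConfig, imprinting: bool = True, exact: bool = False
) -> PopulationState:
    """The ancestral digenic XX/X0 population: monomorphic for every
    ancestral allele, with the imprinting allele g fixed (and all males
    born of imprinting mothers) when ``imprinting`` is true."""
    pairs = []
    for spec in config.loci:
        a = spec.ancestral
        if spec.name == "g" and imprinting:
            a = "g"
        pairs.append((a, a))
    f = female(config, pairs)
    m_pairs = []
    for spec, pair in zip(config.loci, pairs):
        if spec.linkage == X_LINKED:
            m_pairs.append((pair[0], None))
        else:
            m_pairs.append(pair)
    m = male(config, m_pairs, imprinted=imprinting)
    one: Number = Fraction(1) if exact else 1.0
    return PopulationState({f: one}, {m: one}, sex_ratio=one)


def monogenic_state(config: ModelConfig, exact: bool = False) -> PopulationState:
    """The canonical monogenic state: androgenic Ee and gynogenic ee
    females at half frequency each (two-factor; in the one-factor model
    EE is gynogenic and Ee androgenic), four male classes at a quarter
    each, sex ratio 1."""
    half: Number = Fraction(1, 2) if exact else 0.5
    quarter: Number = Fraction(1, 4) if exact else 0.25

    def fixed(spec: LocusSpec) -> str:
        if spec.name == "e":
            raise AssertionError
        if spec.name in ("s", "r", "g", "c"):
            return spec.derived[0]
        return spec.ancestral

    def f_of(e_pair):
        return female(
            config,
            [e_pair if l.name == "e" else (fixed(l), fixed(l)) for l in config.loci],
        )

    def m_of(e_pair):
        return male(
            config,
            [e_pair if l.name == "e" else (fixed(l), fixed(l)) for l in config.loci],
            imprinted=True,
        )

    females = {f_of(("E", "e")): half, f_of(("e", "e")): half}
    if config.variant == ONE_FACTOR:
        females = {f_of(("E", "E")): half, f_of(("E", "e")): half}
    males = {
        m_of(("E", "E")): quarter,
        m_of(("E", "e")): quarter,
        m_of(("e", "E")): quarter,
        m_of(("e", "e")): quarter,
    }
    one: Number = Fraction(1) if exact else 1.0
    return PopulationState(females, males, sex_ratio=one)


# ---------------------------------------------------------------------------
# scenario machinery


@dataclass(frozen=True)
class Stage:
    """One gene-emergence event: introduce an allele and run to
    equilibrium under a selection regime (``None`` means neutral).
    ``carry_forward`` keeps this stage's regime active through all
    later stages."""

    locus: str
    allele: str
    regime: Optional[SelectionRegime] = None
    freq: Number = DEFAULT_INTRO_FREQ
    carry_forward: bool = False
    source_allele: Optional[str] = None


@dataclass(frozen=True)
class Scenario:
    name: str
    config: ModelConfig
    initial: PopulationState
    stages: tuple[Stage, ...]
    tol: float = 1e-10
    max_gens: int = 20000
    #: after the last emergence episode, let the population settle under
    #: neutrality before classifying: a transient viability advantage
    #: drives an invasion but need not persist once the gene is
    #: established, and the canonical final states are the neutral
    #: equilibria.  Presets that study a state *maintained* by ongoing
    #: selection switch this off.
    settle: bool = True

    def __post_init__(self) -> None:
        for stage in self.stages:
            spec = self.config.locus(stage.locus)
            if stage.allele not in spec.alleles:
                raise ModelError(
                    f"stage allele {stage.allele!r} unknown at locus {stage.locus}"
                )


@dataclass
class StageResult:
    stage: Stage
    trajectory: Trajectory
    outcome: str  # digenic / monogenic / mixed / extinct / allele_lost(locus)
    allele_frequency: float
    #: the stage's end state after lost-allele purging (the trajectory's
    #: own final state keeps the raw residues)
    state: PopulationState = None


@dataclass
class ScenarioResult:
    scenario: Scenario
    stages: list[StageResult]
    outcome: str

    @property
    def final(self) -> PopulationState:
        return self.stages[-1].state

    @property
    def reached_monogenic(self) -> bool:
        return self.outcome == "monogenic"


def run_scenario(scenario: Scenario, record_every: int = 50) -> ScenarioResult:
    state = scenario.initial
    carried: list[SelectionRegime] = []
    results: list[StageResult] = []
    outcome = "digenic"
    for stage in scenario.stages:
        state = introduce_allele(
            state,
            scenario.config,
            stage.locus,
            stage.allele,
            stage.freq,
            source_allele=stage.source_allele,
        )
        regimes = list(carried)
        if stage.regime is not None:
            regimes.append(stage.regime)
        selection = SelectionRegime(tuple(e for r in regimes for e in r.entries))
        traj = run_to_equilibrium(
            state,
            selection,
            scenario.config,
            tol=scenario.tol,
            max_gens=scenario.max_gens,
            record_every=record_every,
        )
        state = traj.final
        if traj.extinct:
            outcome = EXTINCT
            results.append(StageResult(stage, traj, EXTINCT, 0.0, state))
            break
        # an allele that decayed below the loss threshold is gone for good:
        # later stages must not re-amplify its float residue
        state = purge_lost_alleles(state, scenario.config)
        freq = state.allele_frequency(scenario.config, stage.locus, stage.allele)
        outcome = classify(state, scenario.config, introduced=(stage.locus, stage.allele))
        results.append(StageResult(stage, traj, outcome, freq, state))
        if stage.carry_forward and stage.regime is not None:
            carried.append(stage.regime)
    else:
        last = scenario.stages[-1] if scenario.stages else None
        had_selection = carried or (last is not None and last.regime is not None)
        if scenario.settle and had_selection:
            traj = run_to_equilibrium(
                state,
                NEUTRAL,
                scenario.config,
                tol=scenario.tol,
                max_gens=2000,
                record_every=record_every,
            )
            state = traj.final
            if traj.extinct:
                outcome = EXTINCT
            else:
                state = purge_lost_alleles(state, scenario.config)
                outcome = classify(
                    state, scenario.config, introduced=(last.locus, last.allele)
                )
            results.append(
                StageResult(
                    Stage(last.locus, last.allele, None),
                    traj,
                    outcome,
                    state.allele_frequency(scenario.config, last.locus, last.allele),
                    state,
                )
            )
    return ScenarioResult(scenario, results, outcome)


def cross(
    mother: Genotype, father: Genotype, config: ModelConfig
) -> dict[Optional[Genotype], Fraction]:
    """Single-pair brood table: egg classes x sperm classes, each
    zygote resolved to its adult fate (``None`` collects dead mass).
    Computed in exact rational arithmetic."""
    if mother.sex != FEMALE or father.sex != MALE:
        raise ModelError("cross() needs one female and one male")
    dist: dict[Optional[Genotype], Fraction] = {}
    for egg in oogenesis(mother, config):
        for sp in spermatogenesis(father, config):
            mass = Fraction(egg.probability) * Fraction(sp.probability)
            for adult, share in resolve(fertilize(egg, sp), config).outcomes:
                dist[adult] = dist.get(adult, Fraction(0)) + mass * Fraction(share)
    return dist


# ---------------------------------------------------------------------------
# the emergence-sequence catalogue


def _stage(locus: str, sel: Optional[str], carry: bool = True,
           mu: Number = 0.1) -> Stage:
    """Stage shorthand: sel is None (neutral), 'rec' or 'dom'.

    Catalogue stages carry their regime forward: a gene's viability
    advantage stays in force while later genes emerge (this is what the
    printed intermediate states reflect, e.g. the sex ratio 1/0.9 of
    the drive state that follows an established eliminator)."""
    allele = locus
    regime = None
    if sel is not None:
        regime = advantage(locus, allele, RECESSIVE if sel == "rec" else DOMINANT, mu)
    return Stage(locus, allele, regime, carry_forward=carry)


#: stage regimes per dominance grid and sequence: the regime under which
#: each emerging gene is analysed (``None`` = no viability advantage).
_GRID_REGIMES: dict[tuple[str, str], dict[str, list[tuple[str, Optional[str]]]]] = {
    # (s dominance, r dominance) -> sequence -> [(locus, selection)]
    (DOMINANT, DOMINANT): {
        "e s r": [("e", None), ("s", "dom"), ("r", "dom")],
        "e r s": [("e", "rec"), ("r", "dom"), ("s", "dom")],
        "s e r": [("s", "dom"), ("e", None), ("r", "dom")],
        "s r e": [("s", "dom"), ("r", "dom"), ("e", None)],
        "r e s": [("r", "dom"), ("e", "rec"), ("s", "dom")],
        "r s e": [("r", "dom"), ("s", "dom"), ("e", None)],
    },
    (DOMINANT, RECESSIVE): {
        "e s r": [("e", None), ("s", "dom"), ("r", "rec")],
        "e r s": [("e", "rec"), ("r", "rec"), ("s", "dom")],
        "s e r": [("s", "dom"), ("e", None), ("r", "rec")],
        "s r e": [("s", "dom"), ("r", "rec"), ("e", None)],
        "r e s": [("r", "rec"), ("e", "rec"), ("s", "dom")],
        "r s e": [("r", "rec"), ("s", "dom"), ("e", "dom")],
    },
    (RECESSIVE, DOMINANT): {
        "e s r": [("e", None), ("s", "rec"), ("r", "dom")],
        "e r s": [("e", "rec"), ("r", "dom"), ("s", "rec")],
        "s e r": [("s", "rec"), ("e", "rec"), ("r", "dom")],
        "s r e": [("s", "rec"), ("r", "dom"), ("e", None)],
        "r e s": [("r", "dom"), ("e", "rec"), ("s", "rec")],
        "r s e": [("r", "dom"), ("s", "rec"), ("e", None)],
    },
    (RECESSIVE, RECESSIVE): {
        "e s r": [("e", None), ("s", "rec"), ("r", "rec")],
        "e r s": [("e", "rec"), ("r", "rec"), ("s", "rec")],
        "s e r": [("s", "rec"), ("e", "rec"), ("r", "rec")],
        "s r e": [("s", "rec"), ("r", "rec"), ("e", "dom")],
        "r e s": [("r", "rec"), ("e", "rec"), ("s", "rec")],
        "r s e": [("r", "rec"), ("s", "rec"), ("e", "dom")],
    },
}

SEQUENCES = ("e s r", "e r s", "s e r", "s r e", "r e s", "r s e")

#: imprinting-acquisition sequences (initial population carries G, no
#: imprinting): where and how the imprinter g itself emerges.
_ACQUISITION: dict[str, list[tuple[str, Optional[str]]]] = {
    "g s r": [("g", None), ("s", "rec"), ("r", "rec")],
    "s g r": [("s", "rec"), ("g", "rec"), ("r", "rec")],
    "s r g": [("s", "rec"), ("r", "rec"), ("g", "rec")],
    "g r s": [("g", None), ("r", "rec"), ("s", "rec")],
    "r g s": [("r", "rec"), ("g", None), ("s", "rec")],
    "e g s": [("e", None), ("g", "rec"), ("s", "rec")],
    "e s g": [("e", None), ("s", "rec"), ("g", "rec")],
}


def dominance_scenarios(
    s_dominance: str, r_dominance: str, sequences: Sequence[str] = SEQUENCES
) -> list[Scenario]:
    """Imprinting-fixed two-factor scenarios for one dominance pair."""
    config = two_factor_config(s_dominance, r_dominance)
    init = ancestral_state(config, imprinting=True)
    regimes = _GRID_REGIMES[(s_dominance, r_dominance)]
    out = []
    tag = f"s-{s_dominance[:3]}/r-{r_dominance[:3]}"
    for seq in sequences:
        stages = tuple(_stage(locus, sel) for locus, sel in regimes[seq])
        out.append(Scenario(f"{tag} ({seq})", config, init, stages))
    return out


def non_imprinting_scenarios() -> list[Scenario]:
    """The same recessive/recessive sequences in a population that never
    imprints (no g locus at all)."""
    config = two_factor_config(RECESSIVE, RECESSIVE, with_g=False)
    init = ancestral_state(config, imprinting=False)
    regimes = _GRID_REGIMES[(RECESSIVE, RECESSIVE)]
    out = []
    for seq in SEQUENCES:
        stages = tuple(_stage(locus, sel) for locus, sel in regimes[seq])
        out.append(Scenario(f"no-imprinting ({seq})", config, init, stages))
    return out


def acquisition_scenarios() -> list[Scenario]:
    """Can imprinting itself be acquired en route?  Initial population
    is ancestral at g (GG) and unimprinted."""
    config = two_factor_config(RECESSIVE, RECESSIVE)
    init = ancestral_state(config, imprinting=False)
    out = []
    for seq, chain in _ACQUISITION.items():
        stages = tuple(_stage(locus, sel) for locus, sel in chain)
        out.append(Scenario(f"acquisition ({seq})", config, init, stages))
    return out


def enhanced_inhibitor_scenario(selection: Optional[str] = "dom") -> Scenario:
    """The e* allele (one dose inactivates two eliminator doses)
    arising by mutation of e in the established monogenic population."""
    config = two_factor_config(RECESSIVE, RECESSIVE)
    init = monogenic_state(config)
    regime = None
    if selection is not None:
        regime = advantage("e", "e*", RECESSIVE if selection == "rec" else DOMINANT)
    stages = (Stage("e", "e*", regime, source_allele="e"),)
    # the e* state is maintained by the allele's ongoing advantage, so it
    # is reported under active selection rather than after settling
    return Scenario(
        f"enhanced-inhibitor ({selection or 'neutral'})",
        config,
        init,
        stages,
        settle=False,
    )


def one_factor_scenarios() -> list[Scenario]:
    config = one_factor_config()
    init = ancestral_state(config, imprinting=True)
    return [
        Scenario(
            "one-factor (e s)",
            config,
            init,
            (_stage("e", None), _stage("s", "rec")),
        ),
        Scenario(
            "one-factor (s e)",
            config,
            init,
            (_stage("s", "rec"), _stage("e", None)),
        ),
    ]


def catalogue() -> list[Scenario]:
    """Every scenario of the emergence grid."""
    out: list[Scenario] = []
    for s_dom in (DOMINANT, RECESSIVE):
        for r_dom in (DOMINANT, RECESSIVE):
            out.extend(dominance_scenarios(s_dom, r_dom))
    out.extend(non_imprinting_scenarios())
    out.extend(acquisition_scenarios())
    out.append(enhanced_inhibitor_scenario("dom"))
    out.extend(one_factor_scenarios())
    return out


@dataclass
class GridResult:
    results: list[ScenarioResult]

    def outcome_table(self) -> list[tuple[str, str, str]]:
        rows = []
        for res in self.results:
            stage_outcomes = "; ".join(
                f"{sr.stage.locus}:{sr.outcome}" for sr in res.stages
            )
            rows.append((res.scenario.name, res.outcome, stage_outcomes))
        return rows


def run_grid(scenarios: Optional[Sequence[Scenario]] = None) -> GridResult:
    if scenarios is None:
        scenarios = catalogue()
    return GridResult([run_scenario(s) for s in scenarios])


def find_scenario(name: str) -> Scenario:
    """Look a scenario up in the catalogue by (case-insensitive) name."""
    for sc in catalogue():
        if sc.name.lower() == name.lower():
            return sc
    raise ModelError(f"no catalogue scenario named {name!r}")


def scenario_from_dict(data: Mapping) -> Scenario:
    """Build a scenario from a structured-text (YAML/JSON) mapping.

    Schema::

        name: my-run
        model: two_factor            # or one_factor
        s_dominance: recessive       # two-factor only
        r_dominance: recessive
        imprinting: fixed            # fixed | ancestral | none
        settle: true
        stages:
          - locus: s                 # allele defaults to the derived allele
            selection: rec           # none | rec | dom
            mu: 0.1
            freq: 0.05
            carry_forward: true
    """
    model = data.get("model", TWO_FACTOR)
    imprinting = data.get("imprinting", "fixed")
    if model == ONE_FACTOR:
        config = one_factor_config()
    else:
        config = two_factor_config(
            data.get("s_dominance", RECESSIVE),
            data.get("r_dominance", RECESSIVE),
            with_g=imprinting != "none",
        )
    init = ancestral_state(config, imprinting=imprinting == "fixed")
    stages = []
    for raw in data.get("stages", ()):
        locus = raw["locus"]
        spec = config.locus(locus)
        allele = raw.get("allele", spec.derived[0])
        sel = raw.get("selection", "none")
        regime = None
        if sel not in ("none", None):
            regime = advantage(
                locus,
                allele,
                RECESSIVE if sel == "rec" else DOMINANT,
                raw.get("mu", 0.1),
            )
        stages.append(
            Stage(
                locus,
                allele,
                regime,
                freq=raw.get("freq", DEFAULT_INTRO_FREQ),
                carry_forward=raw.get("carry_forward", True),
                source_allele=raw.get("source_allele"),
            )
        )
    return Scenario(
        data.get("name", "scenario"),
        config,
        init,
        tuple(stages),
        tol=data.get("tol", 1e-10),
        max_gens=data.get("max_gens", 20000),
        settle=data.get("settle", True),
    )
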