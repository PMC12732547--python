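"""The generation recursion: exact fixed points, conservation, the
pooling identity against a per-pair brute force, and classification."""

from fractions import Fraction

import pytest

from xelim import (
    ExtinctionError,
    NEUTRAL,
    PopulationState,
    advantage,
    ancestral_state,
    brood_profile,
    classify,
    female,
    introduce_allele,
    male,
    monogenic_state,
    next_generation,
    run_to_equilibrium,
)
from xelim.dynamics import purge_lost_alleles
from xelim.gametes import fertilize, oogenesis, spermatogenesis
from xelim.resolution import resolve
from conftest import f_of, m_of


class TestFixedPoints:
    def test_ancestral_population_is_stationary(self, cfg):
        state = ancestral_state(cfg, imprinting=True, exact=True)
        nxt = next_generation(state, NEUTRAL, cfg)
        assert nxt.females == state.females
        assert nxt.males == state.males
        assert nxt.sex_ratio == 1

    def test_monogenic_state_is_an_exact_fixed_point(self, cfg):
        state = monogenic_state(cfg, exact=True)
        nxt = next_generation(state, NEUTRAL, cfg)
        assert nxt.females == state.females
        assert nxt.males == state.males
        assert nxt.sex_ratio == 1

    def test_one_factor_monogenic_state_is_an_exact_fixed_point(self, cfg1):
        state = monogenic_state(cfg1, exact=True)
        nxt = next_generation(state, NEUTRAL, cfg1)
        assert nxt.females == state.females
        assert nxt.males == state.males
        assert nxt.sex_ratio == 1

    def test_drive_state_sex_ratio_under_persisting_advantage(self, cfg):
        """Heterozygous females over eliminator-homozygous males: the
        composition is stationary and a persisting recessive advantage
        for the eliminator prints SR = 1/0.9."""
        f = f_of(cfg, s=("s", "s"), r=("R", "r"))
        m = m_of(cfg, s=("s", "s"), r=("r", "r"))
        state = PopulationState({f: Fraction(1)}, {m: Fraction(1)}, Fraction(1))
        sel = advantage("r", "r", "recessive", Fraction(1, 10))
        nxt = next_generation(state, sel, cfg)
        assert nxt.females == {f: Fraction(1)}
        assert nxt.males == {m: Fraction(1)}
        assert nxt.sex_ratio == Fraction(10, 9)


class TestIntroduction:
    def test_hardy_weinberg_mass_redistribution(self, cfg):
        state = ancestral_state(cfg, imprinting=True, exact=True)
        st = introduce_allele(state, cfg, "e", "e", Fraction(1, 20))
        by_count = {}
        for g, f in st.females.items():
            by_count[g.count(cfg, "e", "e")] = f
        assert by_count == {
            0: Fraction(361, 400),
            1: Fraction(19, 200),
            2: Fraction(1, 400),
        }

    def test_zero_frequency_is_identity(self, cfg):
        state = ancestral_state(cfg, imprinting=True, exact=True)
        st = introduce_allele(state, cfg, "r", "r", 0)
        assert st.females == state.females and st.males == state.males

    def test_full_replacement(self, cfg):
        state = ancestral_state(cfg, imprinting=True, exact=True)
        st = introduce_allele(state, cfg, "r", "r", 1)
        assert all(g.count(cfg, "r", "r") == 2 for g in st.females)

    def test_neutral_allele_frequency_is_invariant(self, cfg):
        """With no functional partner loci an introduced allele sits at
        its Hardy-Weinberg mix and the recursion leaves it untouched
        (exact rational arithmetic)."""
        state = ancestral_state(cfg, imprinting=True, exact=True)
        st = introduce_allele(state, cfg, "e", "e", Fraction(1, 20))
        nxt = next_generation(st, NEUTRAL, cfg)
        for sex in ("females", "males"):
            table_a, table_b = getattr(st, sex), getattr(nxt, sex)
            freq = lambda t: sum(
                f * g.count(cfg, "e", "e") for g, f in t.items()
            )
            assert freq(table_a) == freq(table_b)
        assert nxt.females == next_generation(nxt, NEUTRAL, cfg).females


def brute_force_generation(state, selection, config):
    """Independent recursion: expand every (mother, father, egg, sperm,
    fate) tuple explicitly instead of pooling gametes."""
    females, males = {}, {}
    for mother, fm in state.females.items():
        for father, ff in state.males.items():
            pair_mass = fm * ff
            for egg in oogenesis(mother, config):
                for sp in spermatogenesis(father, config):
                    mass = pair_mass * egg.probability * sp.probability
                    for adult, share in resolve(fertilize(egg, sp), config).survivors():
                        table = females if adult.sex == "female" else males
                        table[adult] = table.get(adult, 0) + mass * share
    for table in (females, males):
        for g in table:
            table[g] *= selection.fitness(g, config)
    fmass, mmass = sum(females.values()), sum(males.values())
    return (
        {g: v / fmass for g, v in females.items()},
        {g: v / mmass for g, v in males.items()},
        mmass / fmass,
    )


class TestPoolingOracle:
    def test_pooled_recursion_equals_per_pair_expansion(self, cfg):
        """Gamete pooling is exact under random mating: compare one full
        generation against the explicit per-pair brute force on a
        two-locus polymorphic state."""
        state = ancestral_state(cfg, imprinting=True, exact=True)
        state = introduce_allele(state, cfg, "e", "e", Fraction(1, 10))
        state = introduce_allele(state, cfg, "r", "r", Fraction(1, 5))
        sel = advantage("r", "r", "recessive", Fraction(1, 10))
        for _ in range(3):
            nxt = next_generation(state, sel, cfg)
            bf_f, bf_m, bf_sr = brute_force_generation(state, sel, cfg)
            assert nxt.females == bf_f
            assert nxt.males == bf_m
            assert nxt.sex_ratio == bf_sr
            state = nxt

    def test_conservation_after_each_generation(self, cfg):
        state = ancestral_state(cfg, imprinting=True, exact=True)
        state = introduce_allele(state, cfg, "r", "r", Fraction(1, 20))
        sel = advantage("r", "r", "recessive", Fraction(1, 10))
        for _ in range(5):
            state = next_generation(state, sel, cfg)
            assert sum(state.females.values()) == 1
            assert sum(state.males.values()) == 1
            assert all(v >= 0 for v in state.females.values())


class TestEquilibrium:
    def test_neutral_introduction_converges_immediately(self, cfg):
        state = ancestral_state(cfg, imprinting=True)
        st = introduce_allele(state, cfg, "e", "e", 0.05)
        traj = run_to_equilibrium(st, NEUTRAL, cfg)
        assert traj.converged and traj.generations <= 2

    def test_selection_placement_matters(self, cfg):
        """Dropping the viability differential removes the published
        drive-selection balance: with mu=0 the aberrant-spermatogenesis
        equilibrium is not the 0.157/0.464/0.378 split."""
        state = introduce_allele(
            ancestral_state(cfg, imprinting=True), cfg, "s", "s", 0.05
        )
        with_sel = run_to_equilibrium(
            state, advantage("s", "s", "recessive", 0.1), cfg
        ).final
        without = run_to_equilibrium(
            state, advantage("s", "s", "recessive", 0.0), cfg
        ).final
        ss = f_of(cfg, s=("s", "s"))
        assert abs(with_sel.females[ss] - 0.378) < 5e-3
        assert abs(without.females.get(ss, 0.0) - 0.378) > 0.05

    def test_extinction_signal_when_males_vanish(self, cfg):
        # imprinted aberrant males only produce X sperm: no sons at all
        f = f_of(cfg, s=("s", "s"))
        m = m_of(cfg, s=("s", "s"))
        state = PopulationState({f: 1.0}, {m: 1.0}, 1.0)
        with pytest.raises(ExtinctionError, match="no males"):
            next_generation(state, NEUTRAL, cfg)
        traj = run_to_equilibrium(state, NEUTRAL, cfg)
        assert traj.extinct == "no males"


class TestClassification:
    def test_ancestral_population_is_digenic(self, cfg):
        assert classify(ancestral_state(cfg, imprinting=True), cfg) == "digenic"

    def test_monogenic_state_is_monogenic(self, cfg):
        state = monogenic_state(cfg)
        assert classify(state, cfg) == "monogenic"
        gyn = f_of(cfg, e=("e", "e"), s=("s", "s"), r=("r", "r"))
        andro = f_of(cfg, e=("E", "e"), s=("s", "s"), r=("r", "r"))
        d, s, _ = brood_profile(gyn, state.males, cfg)
        assert (d, s) == (1, 0)
        d, s, _ = brood_profile(andro, state.males, cfg)
        assert (d, s) == (0, 1)

    def test_coexistence_is_mixed(self, cfg):
        digenic_female = f_of(cfg, s=("s", "s"), r=("R", "r"))
        state = monogenic_state(cfg)
        state.females = {g: 0.4 for g in state.females}
        state.females[digenic_female] = 0.2
        assert classify(state, cfg) == "mixed"

    def test_lost_allele_reported(self, cfg):
        state = ancestral_state(cfg, imprinting=True)
        assert classify(state, cfg, introduced=("r", "r")) == "allele_lost(r)"

    def test_ancestral_brood_is_half_and_half(self, cfg):
        state = ancestral_state(cfg, imprinting=True, exact=True)
        (mother,) = state.females
        d, s, _ = brood_profile(mother, state.males, cfg)
        assert d == Fraction(1, 2) and s == Fraction(1, 2)


def test_purge_removes_residues(cfg):
    state = monogenic_state(cfg)
    ghost = f_of(cfg, s=("S", "s"), r=("r", "r"), e=("e", "e"))
    state.females[ghost] = 1e-9
    total = sum(state.females.values())
    state.females = {g: v / total for g, v in state.females.items()}
    cleaned = purge_lost_alleles(state, cfg)
    assert ghost not in cleaned.females
    assert abs(sum(cleaned.females.values()) - 1) < 1e-12
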