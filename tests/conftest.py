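import pytest
from hypothesis import HealthCheck, settings

from xelim import (
    female,
    male,
    one_factor_config,
    sciara_one_factor_config,
    sciara_two_factor_config,
    two_factor_config,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    """Standard two-factor configuration (s and r recessive, g present)."""
    return two_factor_config()


@pytest.fixture(scope="session")
def cfg1():
    return one_factor_config()


@pytest.fixture(scope="session")
def sciara2():
    return sciara_two_factor_config()


@pytest.fixture(scope="session")
def sciara1():
    return sciara_one_factor_config()


def f_of(config, e=("E", "E"), s=("S", "S"), r=("R", "R"), g=("g", "g")):
    """Female genotype shorthand for the standard two-factor config."""
    pairs = {"e": e, "s": s, "r": r}
    if config.has("g"):
        pairs["g"] = g
    return female(config, pairs)


def m_of(config, e=("E", "E"), s=("S", "S"), r=("R", "R"), g=("g", "g"),
         imprinted=True, x_origin="maternal"):
    pairs = {"e": e, "s": s, "r": r}
    if config.has("g"):
        pairs["g"] = g
    return male(config, pairs, imprinted=imprinted, x_origin=x_origin)


def enumerate_genotypes(config):
    """Every canonical genotype of a configuration (females aggregated,
    males ordered, with both imprint states and X origins)."""
    from itertools import product

    per_locus = []
    for spec in config.loci:
        alleles = spec.alleles
        per_locus.append([(a, b) for a in alleles for b in alleles])
    out = []
    seen = set()
    for combo in product(*per_locus):
        try:
            g = female(config, list(combo))
        except Exception:
            continue
        if g not in seen:
            seen.add(g)
            out.append(g)
    for combo in product(*per_locus):
        for imprinted in (False, True):
            for origin in ("maternal", "paternal"):
                pairs = []
                ok = True
                for spec, pair in zip(config.loci, combo):
                    if spec.linkage == "X_linked":
                        if origin == "maternal":
                            pairs.append((pair[0], None))
                        else:
                            pairs.append((None, pair[1]))
                    else:
                        pairs.append(pair)
                try:
                    g = male(config, pairs, imprinted=imprinted, x_origin=origin)
                except Exception:
                    continue
                if g not in seen:
                    seen.add(g)
                    out.append(g)
    return out
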