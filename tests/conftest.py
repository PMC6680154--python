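import random

import pytest
from hypothesis import HealthCheck, settings

from trilink.genetics import (
    CrossDesign,
    Dominance,
    Locus,
    ParentGenotype,
    Role,
    SHaplotype,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def hih_design():
    from trilink import datasets

    return datasets.okl_s_hih_design()


@pytest.fixture(scope="session")
def sep_design():
    from trilink import datasets

    return datasets.okl_s_sep_design()


def random_three_locus_design(rng: random.Random, with_s: bool = None):
    """A random three-locus testcross design with a valid tester.

    Returns (design, informative, tester).  Dominance modes, locus names and
    phase are randomised; at most one composite S locus.
    """
    if with_s is None:
        with_s = rng.random() < 0.5
    n = 3
    s_pos = rng.randrange(n) if with_s else -1
    loci = []
    for i in range(n):
        name = f"L{i}_{rng.randrange(1000)}"
        if i == s_pos:
            loci.append(Locus(name, Dominance.COMPOSITE_S))
        else:
            mode = rng.choice([Dominance.MUTANT_DOMINANT, Dominance.MUTANT_RECESSIVE])
            loci.append(Locus(name, mode, f"D{i}", f"d{i}"))
    design = CrossDesign(tuple(loci), name="random")

    h1, h2, tester_alleles = [], [], []
    for i, locus in enumerate(loci):
        if locus.dominance is Dominance.COMPOSITE_S:
            a, b = SHaplotype.thrum(), SHaplotype.pin()
            tester_alleles.append(SHaplotype.pin())
        else:
            a, b = locus.dominant_symbol, locus.recessive_symbol
            tester_alleles.append(locus.recessive_symbol)
        if rng.random() < 0.5:
            a, b = b, a
        h1.append(a)
        h2.append(b)
    informative = ParentGenotype("inf", tuple(h1), tuple(h2), Role.INFORMATIVE)
    tester = ParentGenotype("tst", tuple(tester_alleles), tuple(tester_alleles), Role.TESTER)
    return design, informative, tester
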