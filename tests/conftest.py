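import pytest

from glyscreen.fragments import enumerate_fragments, parse_structure_code
from glyscreen.simulate import make_run, study_plants

#: Structure codes of the two galactose-arm isomers of the monogalactosylated
#: core-fucosylated biantennary glycan (differ only in which arm carries Gal).
A1G1F_ARM3 = "GlN(Fuc)GlN Man(Man[a1,3] GlN Gal)(Man[a1,6] GlN)"
A1G1F_ARM6 = "GlN(Fuc)GlN Man(Man[a1,3] GlN)(Man[a1,6] GlN Gal)"


@pytest.fixture(scope="session")
def a1g1f_pair():
    t3 = parse_structure_code(A1G1F_ARM3, "A1G1F(a1,3)")
    t6 = parse_structure_code(A1G1F_ARM6, "A1G1F(a1,6)")
    return t3, t6


@pytest.fixture(scope="session")
def a1g1f_fragments(a1g1f_pair):
    t3, t6 = a1g1f_pair
    return enumerate_fragments(t3), enumerate_fragments(t6)


@pytest.fixture(scope="session")
def study_scenario():
    """The reference planted run: (plants, db, decoys, scans, lc, truth)."""
    plants, db, decoys = study_plants()
    scans, lc, truth = make_run(11, plants, decoy_masses=[d.mass for d in decoys])
    return plants, db, decoys, scans, lc, truth
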