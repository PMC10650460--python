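import pytest

from isomirkit import HairpinRef, MatureAnnotation, ReferenceSet

# Toy reference: a 22-nt mature flanked by short hairpin arms. The mature
# ends ...UGA so one/two/three-base 3' trims are Trim A / Trim AG / Trim AGU,
# and the first downstream hairpin base is G, so an appended A is
# non-templated while an appended G is a templated extension.
TOY_MATURE = "UCCCUGAGACCCUAACUUGUGA"
TOY_HAIRPIN = "CGUA" + TOY_MATURE + "GCUAG"
TOY_START, TOY_END = 4, 26


@pytest.fixture
def toy_hairpin() -> HairpinRef:
    return HairpinRef("toy-mir", TOY_HAIRPIN)


@pytest.fixture
def toy_annot() -> MatureAnnotation:
    return MatureAnnotation("toy-miR-5p", "toy-mir", TOY_START, TOY_END, "5p")


@pytest.fixture
def toy_ref(toy_hairpin, toy_annot) -> ReferenceSet:
    ref = ReferenceSet()
    ref.add_hairpin(toy_hairpin)
    ref.add_mature(toy_annot)
    return ref
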