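import numpy as np
import pytest

from adrminer.dict_ner import MedDRADictionary, expand_terms
from adrminer.synthetic_fixtures import generate_dictionary, generate_labels

# The one worked example carried through the corpus: a Factor mention
# "risk" at section offset 2309 and an AdverseReaction "cancer" at 2318.
EXAMPLE_SENTENCE = (
    "Long-term cumulative radiation exposure is associated with an "
    "increased risk for cancer."
)
EXAMPLE_SENTENCE_START = 2309 - EXAMPLE_SENTENCE.index("risk")

EXAMPLE_LABEL_XML = f"""<Label drug="choline">
  <Text>
    <Section id="S2">{' ' * EXAMPLE_SENTENCE_START}{EXAMPLE_SENTENCE}</Section>
  </Text>
  <Mentions>
    <Mention id="M10" section="S2" type="Factor" start="2309" len="4" str="risk" />
    <Mention id="M11" section="S2" type="AdverseReaction" start="2318" len="6" str="cancer" />
  </Mentions>
  <Reactions>
    <Reaction id="R4" str="cancer">
      <Normalization id="R4.N1" meddra_pt="Neoplasm malignant" meddra_pt_id="10028997" meddra_llt="Cancer" meddra_llt_id="10007050" />
    </Reaction>
  </Reactions>
</Label>
"""


@pytest.fixture
def example_label_xml() -> str:
    return EXAMPLE_LABEL_XML


@pytest.fixture
def mini_dictionary() -> MedDRADictionary:
    """The two-level dictionary implied by the worked example."""
    d = MedDRADictionary()
    d.add_pt("10028997", "Neoplasm malignant")
    d.add_pt("10022095", "Injection site atrophy")
    d.add_llt("10007050", "Cancer", "10028997")
    d.add_llt("10022097", "Atrophy inject site", "10022095")
    d.add_llt("10022098", "Injection site fat atrophy", "10022095")
    return expand_terms(d)


@pytest.fixture(scope="session")
def synth_dictionary():
    return generate_dictionary(n_pt=8, llt_per_pt=3, seed=11)


@pytest.fixture(scope="session")
def synth_labels(synth_dictionary):
    return generate_labels(
        12, synth_dictionary, mention_rate=0.6, irregular_fraction=0.0, seed=12
    )


@pytest.fixture(scope="session")
def synth_labels_irregular(synth_dictionary):
    return generate_labels(
        8, synth_dictionary, mention_rate=0.6, irregular_fraction=0.5, seed=13
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
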