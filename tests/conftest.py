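import pytest

from litmarker.lexicon import EntityType, Term, TermList, build_automaton


@pytest.fixture
def disease_terms() -> TermList:
    return TermList(
        entity_type=EntityType.DISEASE,
        terms=[
            Term(
                "D:CRC",
                EntityType.DISEASE,
                "colorectal cancer",
                ("colorectal cancer", "colorectal carcinoma", "CRC"),
            ),
            Term(
                "D:GE",
                EntityType.DISEASE,
                "gastroenteritis",
                ("gastroenteritis",),
            ),
            Term(
                "D:LC",
                EntityType.DISEASE,
                "liver cirrhosis",
                ("liver cirrhosis", "cirrhosis of the liver"),
            ),
        ],
    )


@pytest.fixture
def microbe_terms() -> TermList:
    return TermList(
        entity_type=EntityType.MICROBIOME,
        terms=[
            Term(
                "M:VP",
                EntityType.MICROBIOME,
                "Vibrio parahaemolyticus",
                ("Vibrio parahaemolyticus", "Vibrio"),
            ),
            Term(
                "M:FN",
                EntityType.MICROBIOME,
                "Fusobacterium nucleatum",
                ("Fusobacterium nucleatum",),
            ),
            Term(
                "M:SP",
                EntityType.MICROBIOME,
                "Streptococcus pneumoniae",
                ("Streptococcus pneumoniae", "s. pneumonia"),
            ),
        ],
    )


@pytest.fixture
def automaton(disease_terms, microbe_terms):
    return build_automaton([disease_terms, microbe_terms])
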