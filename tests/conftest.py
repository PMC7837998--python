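import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hepanlp.corpus import Lexicon
from hepanlp.tagging import ENTITY_TYPES

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: small character pool for generated text (CJK + ASCII mixed content)
CHAR_POOL = "肝脏左右叶动脉期强化明显低密度门快进出扫描未见aA1。，"


def random_legal_tags(rng: np.random.Generator, length: int) -> list[str]:
    """Sample a legal BIO sequence by stitching O-gaps and entity runs."""
    tags: list[str] = []
    while len(tags) < length:
        if rng.random() < 0.5:
            tags.append("O")
        else:
            ent = ENTITY_TYPES[rng.integers(2)]
            run = int(rng.integers(1, 5))
            tags.append(f"B-{ent}")
            tags.extend([f"I-{ent}"] * (run - 1))
    return tags[:length]


def random_text(rng: np.random.Generator, length: int) -> str:
    return "".join(CHAR_POOL[i] for i in rng.integers(0, len(CHAR_POOL), length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def small_lexicon() -> Lexicon:
    return Lexicon(
        entries={
            "肝脏": "Location",
            "肝右叶": "Location",
            "脾脏": "Location",
            "低密度影": "Density",
            "高密度影": "Density",
            "增强扫描未见强化": "Enhancement",
            "环形强化": "Enhancement",
            "形态失常": "Morphology",
            "明显": "Modifier",
            "边界不清": "Modifier",
        },
        synonyms={"肝": "肝脏", "脾": "脾脏"},
    )
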