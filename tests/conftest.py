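import io

import pytest

from emovoc.lexicon import (
    build_stopwords,
    default_category_dictionary,
    default_emotion_lexicon,
    default_stopwords,
    load_emotion_lexicon,
)
from emovoc.textscore import Transcript


@pytest.fixture(scope="session")
def lexicon():
    return default_emotion_lexicon()


@pytest.fixture(scope="session")
def category_dict():
    return default_category_dictionary()


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()


@pytest.fixture
def tiny_lexicon():
    """Hand-written four-base lexicon used where exact counts are traced."""
    tsv = (
        "term\tvariants\tcategory\n"
        "angry\tanger,angrily\tanger\n"
        "scared\t\tanxiety\n"
        "sad\tsadness\tsadness\n"
        "happy\t\tpositive\n"
    )
    return load_emotion_lexicon(io.StringIO(tsv))


@pytest.fixture
def tiny_stopwords():
    return build_stopwords({"the", "a", "i", "i'd", "like", "and"}, {"hmm", "ahm", "ehm"})


def make_transcript(pid="p1", group="NT", **responses):
    """Transcript with explicit item→text responses; unlisted items empty."""
    filled = {i: "" for i in range(1, 18)}
    filled.update({int(k.lstrip("item")): v for k, v in responses.items()})
    return Transcript(participant_id=pid, group=group, responses=filled)


@pytest.fixture
def transcript_factory():
    return make_transcript
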