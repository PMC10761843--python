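import pytest

from herblabel.augmentor import AugmentationConfig, ResourcePack, generate_dataset
from herblabel.corpus_model import AnnotatedDocument, EntityLabel, EntitySpan


@pytest.fixture(scope="session")
def resources() -> ResourcePack:
    return ResourcePack.builtin()


@pytest.fixture(scope="session")
def small_artificial_corpus(resources) -> list[AnnotatedDocument]:
    return generate_dataset(AugmentationConfig(n_records=60, seed=7), resources)


@pytest.fixture
def toy_docs() -> list[AnnotatedDocument]:
    return [
        AnnotatedDocument(
            doc_id="t1",
            text="Salvia japonica",
            spans=(EntitySpan(0, 15, EntityLabel.EN_NAME),),
            source="manual",
            collector="Takahashi, K.",
        ),
        AnnotatedDocument(
            doc_id="t2",
            text="兵庫県三田市 1979/4/1",
            spans=(
                EntitySpan(0, 3, EntityLabel.JA_PREF),
                EntitySpan(3, 6, EntityLabel.JA_CITY),
                EntitySpan(7, 15, EntityLabel.DATE),
            ),
            source="manual",
            collector="田中 太郎",
        ),
        AnnotatedDocument(
            doc_id="t3",
            text="leg. S. Sato, No. 3911",
            spans=(
                EntitySpan(5, 12, EntityLabel.PERSON),
                EntitySpan(18, 22, EntityLabel.NUMBER),
            ),
            source="manual",
            collector="S. Sato",
        ),
    ]
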