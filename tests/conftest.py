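import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from anatomap import FixtureSource, Resources, load_ontology

# worked-example explanation texts (synthetic stand-ins for encyclopedia
# lead paragraphs, written for this suite)
EXPLANATIONS = {
    "sigmoidoscopy": (
        "Sigmoidoscopy is the minimally invasive medical examination of the "
        "sigmoid colon, the nearest segment of the large intestine, and may "
        "extend to the rectum."
    ),
    "electrocardiography": (
        "Electrocardiography records the electrical activity of the heart "
        "using electrodes placed on the chest. The heart generates small "
        "electrical changes that are detected across the thorax during each "
        "heartbeat."
    ),
    "colonoscopy": (
        "Colonoscopy is the endoscopic examination of the colon and the "
        "distal part of the small intestine with a camera."
    ),
}


@pytest.fixture(scope="session")
def onto():
    return load_ontology()


@pytest.fixture(scope="session")
def resources():
    return Resources.default()


@pytest.fixture(scope="session")
def kb_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("kb")
    for term, text in EXPLANATIONS.items():
        (d / f"{term}.txt").write_text(text, encoding="utf-8")
    return d


@pytest.fixture()
def kb_source(kb_dir, resources):
    return FixtureSource(kb_dir, stopwords=resources.stopwords)
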