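import pytest

from bcrep import (
    AnnotationParams,
    annotate_repertoire,
    build_default_germline,
    get_preset,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def germline():
    return build_default_germline()


@pytest.fixture(scope="session")
def ctrl_small(germline):
    """500 ctrl cells: (cells, reads, manifest, annotations)."""
    cells, reads, manifest = simulate_repertoire(
        germline, get_preset("ctrl"), 500, seed=42
    )
    annotations = annotate_repertoire(reads, germline)
    return cells, reads, manifest, annotations


@pytest.fixture(scope="session")
def annotation_params():
    return AnnotationParams()
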