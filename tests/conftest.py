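from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from phenogo.network import AnnotationNetwork, StudyKey

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def sk(i: int) -> StudyKey:
    return StudyKey(pmid=f"p{i}", allele_id="a")


@pytest.fixture
def toy_network() -> AnnotationNetwork:
    """The worked micro-example: N=6, PM(MP1)={s1,s2,s3}, PM(MP2)={s1,s2},
    PM(GO1)={s1,s2,s4}."""
    return AnnotationNetwork.from_sets(
        {
            "MP:0000001": {sk(1), sk(2), sk(3)},
            "MP:0000002": {sk(1), sk(2)},
        },
        {"GO:0000001": {sk(1), sk(2), sk(4)}},
        universe=[sk(i) for i in range(1, 7)],
    )


@pytest.fixture
def tiny_obo(tmp_path):
    """A diamond is_a DAG: root -> a -> c, root -> b -> c, plus root -> c direct."""
    text = """format-version: 1.2
ontology: tiny

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: a
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: b
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: c
is_a: GO:0000002 ! a
is_a: GO:0000003 ! b
is_a: GO:0000001 ! root
"""
    path = tmp_path / "tiny.obo"
    path.write_text(text)
    return path
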