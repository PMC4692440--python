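"""Shared fixtures: toy instances, small OWL/RDF documents, TSV writers."""

from __future__ import annotations

import textwrap

import pytest

from alignrepair import fig1_fixture, fig2_fixture

#: base IRI for test OWL documents (relative references resolve against it)
OWL_BASE = "http://t/"

RDF_HEAD = textwrap.dedent(
    f"""\
    <?xml version="1.0"?>
    <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
             xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
             xmlns:owl="http://www.w3.org/2002/07/owl#"
             xml:base="{OWL_BASE}">
    """
)
RDF_TAIL = "</rdf:RDF>\n"


def owl_doc(body: str) -> str:
    return RDF_HEAD + textwrap.dedent(body) + RDF_TAIL


@pytest.fixture(scope="session")
def fig1():
    return fig1_fixture()


@pytest.fixture(scope="session")
def fig2():
    return fig2_fixture()


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name: str, text: str):
        p = tmp_path / name
        p.write_text(textwrap.dedent(text), encoding="utf-8")
        return p

    return _write


@pytest.fixture
def write_owl(tmp_path):
    def _write(name: str, body: str):
        p = tmp_path / name
        p.write_text(owl_doc(body), encoding="utf-8")
        return p

    return _write
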