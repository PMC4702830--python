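import numpy as np
import pytest

from kbforge.corpus import Document
from kbforge.dictionaries import Concept, Dictionary


def make_dictionary(name, category, concept_terms, preferred=None):
    """concept_terms: {concept_id: iterable of term strings}."""
    d = Dictionary(name=name, category=category)
    for cid, terms in concept_terms.items():
        terms = set(terms)
        pref = (preferred or {}).get(cid, sorted(terms)[0])
        d.concepts[cid] = Concept(concept_id=cid, preferred_name=pref,
                                  dictionary=name, category=category,
                                  terms=terms | {pref})
    return d


@pytest.fixture
def enzyme_dictionary():
    return make_dictionary("Enzymes", "chemicals", {
        "E1": {"isocitrate lyase"},
        "E2": {"malate synthase", "synthase"},
        "E3": {"beta-lactamase"},
        "E4": {"ACE"},
    })


@pytest.fixture
def taxa_dictionary():
    return make_dictionary("Taxa", "taxonomy", {
        "T1": {"saccharomyces cerevisiae", "s cerevisiae"},
        "T2": {"mycobacterium tuberculosis"},
    })


@pytest.fixture
def small_corpus():
    return [
        Document("D1", "Isocitrate lyase is induced",
                 "The enzyme malate synthase acts with isocitrate lyase in "
                 "Saccharomyces cerevisiae cultures."),
        Document("D2", "ACE and beta-lactamase",
                 "Reports on beta lactamase and ace in Mycobacterium tuberculosis."),
        Document("D3", "Growth medium assay",
                 "Nothing of note appears in this control document."),
        Document("D4", "Synthase kinetics",
                 "Repeated synthase synthase mentions with isocitrate lyase."),
    ]


def write_dictionary_tsv(path, rows):
    """rows: iterables matching the unified dictionary column order."""
    header = ("concept_id\tdictionary_name\tdictionary_category\t"
              "preferred_name\tterm\tsource_id\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for row in rows:
            fh.write("\t".join(row) + "\n")


@pytest.fixture
def dictionary_tsv(tmp_path):
    path = tmp_path / "enzymes.tsv"
    write_dictionary_tsv(path, [
        ("E1", "Enzymes", "chemicals", "isocitrate lyase", "isocitrate lyase", "EC:4.1.3.1"),
        ("E1", "Enzymes", "chemicals", "isocitrate lyase", "icl", "EC:4.1.3.1"),
        ("E2", "Enzymes", "chemicals", "malate synthase", "malate synthase", "EC:2.3.3.9"),
    ])
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
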