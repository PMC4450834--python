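"""Small built-in worked examples.

A hand-encoded fragment of a liver-finding is-a hierarchy, a three-report
cohort, and a 12-abstract corpus small enough to count by hand.  These are
synthetic teaching fixtures shaped like the real clinical inputs (SNOMED CT
fragments, radiology report extracts, literature abstracts); they are used
throughout the documentation and tests.
"""

from __future__ import annotations

from ontosim.ontology import Concept, OntologyGraph
from ontosim.vectors import Report

__all__ = ["liver_hierarchy", "liver_reports", "liver_corpus", "DISEASE_NAMES"]

DISEASE_NAMES = ("hepatocellular carcinoma", "HCC")


def liver_hierarchy() -> OntologyGraph:
    """An 11-concept is-a fragment around liver findings.

    Levels below the root::

        0  root
        1  clinical finding
        2  finding by site
        3  finding of abdomen
        4  liver finding | abdominal organ finding | fatty liver
        5  disorder of liver | disorder of spleen
        6  hepatic fibrosis | splenomegaly
        7  cirrhosis

    "fatty liver" has two parents (finding of abdomen, liver finding); its
    level is the minimum over upward paths, which keeps it at level 4.  The
    fragment exercises all three distance rules: "cirrhosis" sits 3 links
    under "liver finding", "hepatic fibrosis" 2 links, "splenomegaly" is not
    a descendant of "liver finding" at all (distance unreachable) but sits 2
    links under "abdominal organ finding", and "fatty liver" is itself a
    feature concept (distance 0 to itself).
    """
    concepts = [
        Concept("root", "SNOMED CT concept"),
        Concept("clinical-finding", "clinical finding"),
        Concept("finding-by-site", "finding by site"),
        Concept("abdominal-finding", "finding of abdomen"),
        Concept("liver-finding", "liver finding"),
        Concept("abdominal-organ-finding", "abdominal organ finding"),
        Concept("fatty-liver", "fatty liver", ("hepatic steatosis",)),
        Concept("disorder-of-liver", "disorder of liver"),
        Concept("disorder-of-spleen", "disorder of spleen"),
        Concept("hepatic-fibrosis", "hepatic fibrosis", ("fibrosis of liver",)),
        Concept("splenomegaly", "splenomegaly", ("enlarged spleen",)),
        Concept("cirrhosis", "cirrhosis", ("cirrhosis of liver",)),
    ]
    edges = [
        ("clinical-finding", "root"),
        ("finding-by-site", "clinical-finding"),
        ("abdominal-finding", "finding-by-site"),
        ("liver-finding", "abdominal-finding"),
        ("abdominal-organ-finding", "abdominal-finding"),
        ("fatty-liver", "abdominal-finding"),
        ("fatty-liver", "liver-finding"),
        ("disorder-of-liver", "liver-finding"),
        ("disorder-of-spleen", "abdominal-organ-finding"),
        ("hepatic-fibrosis", "disorder-of-liver"),
        ("splenomegaly", "disorder-of-spleen"),
        ("cirrhosis", "hepatic-fibrosis"),
    ]
    return OntologyGraph(concepts, edges)


def liver_reports() -> list[Report]:
    """Three tiny reports over the liver fragment (two HCC, one NAD)."""
    return [
        Report("r1", "HCC", frozenset({"cirrhosis", "fatty-liver"})),
        Report("r2", "HCC", frozenset({"hepatic-fibrosis"})),
        Report("r3", "NAD", frozenset({"splenomegaly"})),
    ]


def liver_corpus() -> dict[str, str]:
    """Twelve hand-countable abstracts.

    Mention counts (case-insensitive whole phrases, synonyms included):
    disease group 8 (a01-a08); cirrhosis group 4 jointly with disease
    (a01-a04); hepatic fibrosis group 2 jointly (a05, a06); splenomegaly
    1 jointly (a07); fatty liver 2 jointly (a07, a08; a09 mentions it
    without the disease).
    """
    return {
        "a01": "Cirrhosis preceded hepatocellular carcinoma in this cohort.",
        "a02": "HCC arising in cirrhosis of liver remains common.",
        "a03": "Screening for hepatocellular carcinoma in cirrhosis patients.",
        "a04": "Cirrhosis and HCC share etiologies.",
        "a05": "Hepatic fibrosis progression predicts hepatocellular carcinoma.",
        "a06": "Fibrosis of liver staging before HCC resection.",
        "a07": "Splenomegaly and fatty liver noted alongside hepatocellular carcinoma.",
        "a08": "Hepatic steatosis may precede HCC in metabolic disease.",
        "a09": "Fatty liver without malignancy in the control arm.",
        "a10": "Enlarged spleen in portal hypertension without tumour.",
        "a11": "Normal abdominal imaging in the reference group.",
        "a12": "Cirrhosis managed conservatively; no malignancy found.",
    }
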