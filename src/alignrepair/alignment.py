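"""Alignment I/O and the extension of the Horn theory with mapping rules.

A mapping is a cross-ontology correspondence between one class of ontology 1
and one class of ontology 2, carrying a relation (equivalence or one of the
two subsumption directions) and a confidence in [0, 1].  Equivalence
mappings are indivisible: they contribute rules in both directions but are
removed (or kept) as a unit during repair, never split into two subsumption
mappings.

Supported serializations are the INRIA Alignment Format (RDF/XML with
``Cell/entity1/entity2/relation/measure``) and a tab-separated dialect
``source_iri  target_iri  relation  confidence`` with relation symbols
``=`` (equivalence), ``<`` (source subsumed by target) and ``>`` (target
subsumed by source).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator
from xml.sax.saxutils import escape

from .errors import InputError
from .ontology import ClassRef, HornTheory, OntologyGraph

logger = logging.getLogger(__name__)


class Relation(enum.Enum):
    EQUIVALENCE = "="
    SUBSUMED_BY = "<"  # source ⊆ target
    SUBSUMES = ">"  # target ⊆ source

    @classmethod
    def from_symbol(cls, symbol: str) -> "Relation":
        try:
            return cls(symbol.strip())
        except ValueError:
            raise InputError(f"unknown relation symbol {symbol!r}") from None


@dataclass(frozen=True)
class Mapping:
    """One correspondence between a class of ontology 1 and one of ontology 2."""

    source: ClassRef
    target: ClassRef
    relation: Relation = Relation.EQUIVALENCE
    confidence: float = 1.0

    def __post_init__(self):
        if self.source.ontology_id != 1 or self.target.ontology_id != 2:
            raise ValueError("mapping must link ontology 1 (source) to ontology 2 (target)")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source.iri, self.target.iri)

    def rules(self) -> tuple[tuple[ClassRef, ClassRef], ...]:
        """Directed unary Horn rules contributed by this mapping."""
        if self.relation is Relation.EQUIVALENCE:
            return ((self.source, self.target), (self.target, self.source))
        if self.relation is Relation.SUBSUMED_BY:
            return ((self.source, self.target),)
        return ((self.target, self.source),)


class Alignment:
    """An ordered, duplicate-free collection of mappings.

    Duplicate (source, target) pairs keep the highest-confidence entry while
    preserving the input position of the first occurrence.  ``dropped``
    counts input rows discarded because they referenced unknown classes.
    """

    def __init__(self, mappings: Iterator[Mapping] | list[Mapping] = (), dropped: int = 0):
        self._by_key: dict[tuple[str, str], Mapping] = {}
        self.dropped = dropped
        for m in mappings:
            self.add(m)

    def add(self, m: Mapping) -> None:
        existing = self._by_key.get(m.key)
        if existing is None:
            self._by_key[m.key] = m
        elif m.confidence > existing.confidence:
            self._by_key[m.key] = m  # dict preserves first-insertion order

    @property
    def mappings(self) -> list[Mapping]:
        return list(self._by_key.values())

    def without(self, removed) -> "Alignment":
        removed = set(removed)
        return Alignment([m for m in self if m not in removed])

    def __iter__(self) -> Iterator[Mapping]:
        return iter(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, m: Mapping) -> bool:
        return self._by_key.get(m.key) == m

    def __eq__(self, other) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self._by_key == other._by_key  # content equality; order may differ

    def __repr__(self) -> str:
        return f"Alignment({len(self)} mappings)"


# ---------------------------------------------------------------------------
# reading


def read_alignment(
    path: str | Path,
    format: str,
    o1: OntologyGraph,
    o2: OntologyGraph,
) -> Alignment:
    """Read an alignment, dropping (and counting) rows whose classes are not
    present in the given ontologies.  Missing confidences default to 1.0."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    if format == "tsv":
        rows = _read_tsv(path)
    elif format == "alignment_rdf":
        rows = _read_alignment_rdf(path)
    else:
        raise InputError(f"unknown alignment format {format!r}")

    known1 = {c.iri for c in o1.classes}
    known2 = {c.iri for c in o2.classes}
    alignment = Alignment()
    for src_iri, tgt_iri, relation, confidence in rows:
        if src_iri not in known1 or tgt_iri not in known2:
            unknown = src_iri if src_iri not in known1 else tgt_iri
            logger.warning("dropping mapping with unknown class %s", unknown)
            alignment.dropped += 1
            continue
        alignment.add(
            Mapping(ClassRef(src_iri, 1), ClassRef(tgt_iri, 2), relation, confidence)
        )
    if len(alignment) == 0:
        logger.warning("alignment %s is empty after filtering", path)
    return alignment


def _read_tsv(path: Path) -> list[tuple[str, str, Relation, float]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise InputError(f"{path}:{lineno}: expected 3 or 4 tab-separated fields")
            src, tgt, rel = fields[0].strip(), fields[1].strip(), fields[2]
            try:
                conf = float(fields[3]) if len(fields) == 4 else 1.0
            except ValueError:
                raise InputError(f"{path}:{lineno}: bad confidence {fields[3]!r}") from None
            rows.append((src, tgt, Relation.from_symbol(rel), conf))
    return rows


_ALIGN_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment"


def _read_alignment_rdf(path: Path) -> list[tuple[str, str, Relation, float]]:
    import rdflib
    from rdflib import RDF, URIRef

    g = rdflib.Graph()
    try:
        g.parse(str(path), format="xml")
    except Exception as exc:
        raise InputError(f"failed to parse alignment RDF file {path}: {exc}") from exc

    ns = rdflib.Namespace(_ALIGN_NS + "#")
    rows = []
    for cell in g.subjects(RDF.type, ns.Cell):
        e1 = g.value(cell, ns.entity1)
        e2 = g.value(cell, ns.entity2)
        if not isinstance(e1, URIRef) or not isinstance(e2, URIRef):
            raise InputError(f"alignment cell without entity resources in {path}")
        rel_node = g.value(cell, ns.relation)
        rel = Relation.from_symbol(str(rel_node)) if rel_node is not None else Relation.EQUIVALENCE
        measure = g.value(cell, ns.measure)
        conf = float(measure) if measure is not None else 1.0
        rows.append((str(e1), str(e2), rel, conf))
    # rdflib iteration order is not stable; normalize to input-independent order
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows


# ---------------------------------------------------------------------------
# writing


def write_alignment(a: Alignment, path: str | Path, format: str) -> None:
    """Serialize ``a``; confidences keep enough digits to round-trip exactly."""
    path = Path(path)
    if format == "tsv":
        lines = ["# source_iri\ttarget_iri\trelation\tconfidence"]
        for m in a:
            lines.append(
                f"{m.source.iri}\t{m.target.iri}\t{m.relation.value}\t{m.confidence!r}"
            )
        text = "\n".join(lines) + "\n"
    elif format == "alignment_rdf":
        text = _to_alignment_rdf(a)
    else:
        raise InputError(f"unknown alignment format {format!r}")
    try:
        path.write_text(text, encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write alignment to {path}: {exc}") from exc


def _to_alignment_rdf(a: Alignment) -> str:
    cells = []
    for m in a:
        cells.append(
            "  <map>\n"
            "    <Cell>\n"
            f'      <entity1 rdf:resource="{escape(m.source.iri, {chr(34): "&quot;"})}"/>\n'
            f'      <entity2 rdf:resource="{escape(m.target.iri, {chr(34): "&quot;"})}"/>\n'
            f"      <relation>{escape(m.relation.value)}</relation>\n"
            f'      <measure rdf:datatype="http://www.w3.org/2001/XMLSchema#float">'
            f"{m.confidence!r}</measure>\n"
            "    </Cell>\n"
            "  </map>"
        )
    body = "\n".join(cells)
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        f'<rdf:RDF xmlns="{_ALIGN_NS}#"\n'
        '         xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#">\n'
        '<Alignment rdf:about="">\n'
        "  <xml>yes</xml>\n"
        "  <level>0</level>\n"
        "  <type>??</type>\n"
        f"{body}\n"
        "</Alignment>\n"
        "</rdf:RDF>\n"
    )


# ---------------------------------------------------------------------------
# Horn-theory extension


def encode_alignment(t1: HornTheory, t2: HornTheory, m: Alignment) -> HornTheory:
    """Union of both ontology theories plus one rule per subsumption mapping
    and two per equivalence mapping, each tagged with its originating mapping."""
    unary = set(t1.unary_rules) | set(t2.unary_rules)
    mapping_rules: dict[tuple[ClassRef, ClassRef], Mapping] = {}
    for mapping in m:
        for rule in mapping.rules():
            unary.add(rule)
            mapping_rules[rule] = mapping
    return HornTheory(
        unary_rules=frozenset(unary),
        multi_rules=t1.multi_rules | t2.multi_rules,
        false_rules=t1.false_rules | t2.false_rules,
        mapping_rules=mapping_rules,
    )
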