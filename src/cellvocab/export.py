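"""Exporting vocabulary trees as RDF graphs and XML schema.

The folder hierarchy carries exactly one piece of structure — "this term
sits under that one" — so the RDF export uses a single generic
``narrowerTerm`` predicate (SKOS-like) rather than inventing richer
semantics the vocabulary never asserts.  Node IRIs are slash-joined
normalized paths under a configurable base IRI, and each node keeps its raw
label as an ``rdfs:label``, which makes the export lossless: a tree can be
reconstructed from its graph.

The XSD export mirrors the hierarchy as nested element declarations; leaf
tokens become string-typed elements.  Labels that are not valid XML names
(spaces, leading digits) are emitted via their normalized key, with the raw
label preserved in an ``xs:annotation``.
"""

from __future__ import annotations

from lxml import etree
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDFS

from .vocabulary import TermNode, VocabularyTree, add_path, normalize_term

DEFAULT_BASE_IRI = "http://example.org/cellvocab/"

XS = "http://www.w3.org/2001/XMLSchema"
XS_NS = {"xs": XS}


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def _node_iri(base: str, npath: tuple[str, ...]) -> URIRef:
    return URIRef(base + "/".join(npath))


def to_rdf(tree: VocabularyTree, base_iri: str = DEFAULT_BASE_IRI) -> Graph:
    """Convert a tree to an RDF graph: one ``narrowerTerm`` triple per
    parent→child edge (so hierarchy-triple count = node count − root count),
    plus one ``rdfs:label`` per node carrying the raw label."""
    ns = Namespace(base_iri)
    g = Graph()
    g.bind("cv", ns)
    g.bind("rdfs", RDFS)
    for labels, node in tree.walk():
        npath = tuple(normalize_term(l, tree.stop_words) for l in labels)
        iri = _node_iri(base_iri, npath)
        g.add((iri, RDFS.label, Literal(node.label)))
        if node.example_value:
            g.add((iri, ns.exampleValue, Literal(node.example_value)))
        for child in node.children:
            g.add((iri, ns.narrowerTerm,
                   _node_iri(base_iri, npath + (child.normalized_key,))))
    return g


def hierarchy_triples(graph: Graph, base_iri: str = DEFAULT_BASE_IRI) -> int:
    ns = Namespace(base_iri)
    return sum(1 for _ in graph.triples((None, ns.narrowerTerm, None)))


def serialize_rdf(graph: Graph, fmt: str = "turtle") -> str:
    """Serialize to Turtle (``turtle``) or RDF/XML (``xml``)."""
    return graph.serialize(format=fmt)


def tree_from_rdf(graph: Graph, base_iri: str = DEFAULT_BASE_IRI) -> VocabularyTree:
    """Rebuild a vocabulary tree from an exported graph.

    Roots are the subjects that never appear as a ``narrowerTerm`` object;
    labels come from ``rdfs:label``.  Round trip preserves the normalized
    path set exactly.
    """
    ns = Namespace(base_iri)
    labels = {s: str(o) for s, _, o in graph.triples((None, RDFS.label, None))}
    values = {s: str(o) for s, _, o in graph.triples((None, ns.exampleValue, None))}
    children: dict[URIRef, list[URIRef]] = {}
    has_parent: set[URIRef] = set()
    for s, _, o in graph.triples((None, ns.narrowerTerm, None)):
        children.setdefault(s, []).append(o)
        has_parent.add(o)
    nodes = set(labels) | set(children) | has_parent
    roots = sorted(n for n in nodes if n not in has_parent)

    tree = VocabularyTree()

    def visit(iri: URIRef, path: tuple[str, ...]) -> None:
        label = labels.get(iri, str(iri).rsplit("/", 1)[-1])
        new_path = path + (label,)
        add_path(tree, new_path, example_value=values.get(iri),
                 on_collision="ignore")
        for child in sorted(children.get(iri, [])):
            visit(child, new_path)

    for root in roots:
        visit(root, ())
    return tree


# ---------------------------------------------------------------------------
# XML Schema
# ---------------------------------------------------------------------------

def _xml_name(node: TermNode) -> str:
    # NCNames cannot start with a digit; normalized keys are [a-z0-9]+
    key = node.normalized_key
    return key if not key[0].isdigit() else "_" + key


def _annotate(element: etree._Element, label: str) -> None:
    ann = etree.SubElement(element, f"{{{XS}}}annotation")
    doc = etree.SubElement(ann, f"{{{XS}}}documentation")
    doc.text = label


def _emit(parent: etree._Element, node: TermNode) -> None:
    element = etree.SubElement(parent, f"{{{XS}}}element", name=_xml_name(node))
    _annotate(element, node.label)
    if node.is_leaf():
        element.set("type", "xs:string")
        return
    ctype = etree.SubElement(element, f"{{{XS}}}complexType")
    seq = etree.SubElement(ctype, f"{{{XS}}}sequence")
    for child in node.children:
        _emit(seq, child)


def to_xml_schema(tree: VocabularyTree) -> etree._ElementTree:
    """Mirror the folder hierarchy as nested XSD element declarations.

    Each node contributes exactly one ``xs:element`` (element count = node
    count); the raw label rides in an annotation, and the resulting document
    is a valid schema (it compiles against the XML Schema metaschema).
    """
    schema = etree.Element(f"{{{XS}}}schema", nsmap={"xs": XS})
    for root in tree.roots:
        _emit(schema, root)
    return etree.ElementTree(schema)


def element_count(doc: etree._ElementTree) -> int:
    return sum(1 for _ in doc.getroot().iter(f"{{{XS}}}element"))


def validate_schema(doc: etree._ElementTree) -> bool:
    """True iff the document is a well-formed XML Schema."""
    etree.XMLSchema(doc)  # raises on an invalid schema
    return True


def serialize_schema(doc: etree._ElementTree) -> str:
    return etree.tostring(doc, pretty_print=True, encoding="unicode")
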