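"""OWL 2 persistence of the anatomy hierarchy and fitted models.

Each region becomes an ``owl:Class`` with ``rdfs:subClassOf`` matching the
anatomical parent, in the style of a formal neuroanatomy ontology.
Structural attributes (segmentation IDs, laterality, tissue class, layout
order), external-ontology links (``rdfs:seeAlso``) and — when a fitted
:class:`~neuroprofile.normative.NormativeModelSet` is supplied — the raw
regression coefficients and residual SD are attached as annotation
properties, so a generic OWL tool can inspect the normative model.
Subject measurements and w-scores can be serialized as class instances
with data properties.  RDF/XML is the primary format; Turtle also works.
"""

from __future__ import annotations

from pathlib import Path

from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, XSD, URIRef

from .atlas import RegionHierarchy, RegionNode
from .normative import (COVARIATE_NAMES, NormativeModel, NormativeModelSet,
                        WScoreProfile)

NP = Namespace("https://w3id.org/neuroprofile/atlas#")

_MEASURES = ("volume", "thickness")


class OntologyError(ValueError):
    """Vocabulary mismatch or inconsistency while reading/writing OWL."""


def _coef_props(measure: str) -> list[URIRef]:
    return [NP[f"{measure}_coef_{name}"] for name in COVARIATE_NAMES]


def to_owl(hierarchy: RegionHierarchy,
           models: NormativeModelSet | None = None,
           profiles: list[WScoreProfile] | None = None,
           path: str | Path | None = None,
           format: str = "xml") -> Graph:
    """Serialize hierarchy (+ optional models, subject profiles) to OWL.

    Returns the rdflib graph; writes it to ``path`` when given.
    ``format`` is an rdflib serialization name ("xml" = RDF/XML, "turtle").
    """
    if models is not None:
        for rid, _measure in models.models:
            if rid not in hierarchy.nodes:
                raise OntologyError(
                    f"model for unknown region {rid!r}")
    g = Graph()
    g.bind("np", NP)
    g.bind("owl", OWL)
    onto = NP[""]
    g.add((onto, RDF.type, OWL.Ontology))
    g.add((onto, NP.atlasName, Literal(hierarchy.name)))
    g.add((onto, NP.rootId, Literal(hierarchy.root_id)))

    for rid in hierarchy.traversal_order():
        node = hierarchy.nodes[rid]
        cls = NP[rid]
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.label, Literal(node.display_name)))
        if node.parent_id is not None:
            g.add((cls, RDFS.subClassOf, NP[node.parent_id]))
        g.add((cls, NP.laterality, Literal(node.laterality)))
        g.add((cls, NP.tissueClass, Literal(node.tissue_class)))
        g.add((cls, NP.orderIndex,
               Literal(node.order_index, datatype=XSD.integer)))
        for code in node.segmentation_ids:
            g.add((cls, NP.segmentationId,
                   Literal(code, datatype=XSD.integer)))
        for name in node.struct_names:
            g.add((cls, NP.structName, Literal(name)))
        for key, text in node.annotations.items():
            prop = RDFS.seeAlso if key == "seeAlso" else RDFS.comment
            g.add((cls, prop, Literal(text)))
        if models is not None:
            for measure in _MEASURES:
                model = models.models.get((rid, measure))
                if model is None:
                    continue
                for prop, value in zip(_coef_props(measure),
                                       model.coefficients):
                    g.add((cls, prop,
                           Literal(float(value), datatype=XSD.double)))
                g.add((cls, NP[f"{measure}_residual_sd"],
                       Literal(float(model.residual_sd),
                               datatype=XSD.double)))
                g.add((cls, NP[f"{measure}_n_train"],
                       Literal(int(model.n_train), datatype=XSD.integer)))

    for profile in profiles or []:
        for (rid, measure), w in profile.scores.items():
            ind = NP[f"obs_{profile.subject_id}_{rid}"]
            g.add((ind, RDF.type, NP[rid]))
            g.add((ind, NP.subjectId, Literal(profile.subject_id)))
            g.add((ind, NP[f"{measure}_wscore"],
                   Literal(float(w), datatype=XSD.double)))
            raw = profile.raw_values.get((rid, measure))
            if raw is not None:
                g.add((ind, NP[f"{measure}_raw"],
                       Literal(float(raw), datatype=XSD.double)))

    if path is not None:
        g.serialize(destination=str(path), format=format)
    return g


def _opt(g: Graph, subject: URIRef, prop: URIRef):
    return g.value(subject, prop)


def from_owl(source: str | Path | Graph
             ) -> tuple[RegionHierarchy, NormativeModelSet | None]:
    """Parse a document written by :func:`to_owl`; re-validate invariants."""
    if isinstance(source, Graph):
        g = source
    else:
        g = Graph()
        g.parse(str(source))

    root_lit = g.value(NP[""], NP.rootId)
    atlas_name = g.value(NP[""], NP.atlasName)
    nodes: dict[str, RegionNode] = {}
    ns = str(NP)
    for cls in g.subjects(RDF.type, OWL.Class):
        uri = str(cls)
        if not uri.startswith(ns):
            continue
        rid = uri[len(ns):]
        label = _opt(g, cls, RDFS.label)
        if label is None:
            raise OntologyError(f"class {rid}: missing rdfs:label property")
        parent = g.value(cls, RDFS.subClassOf)
        parent_id = str(parent)[len(ns):] if parent is not None else None
        for prop, msg in ((NP.laterality, "np:laterality"),
                          (NP.tissueClass, "np:tissueClass"),
                          (NP.orderIndex, "np:orderIndex")):
            if _opt(g, cls, prop) is None:
                raise OntologyError(f"class {rid}: missing {msg} property")
        ann: dict[str, str] = {}
        see = _opt(g, cls, RDFS.seeAlso)
        if see is not None:
            ann["seeAlso"] = str(see)
        comment = _opt(g, cls, RDFS.comment)
        if comment is not None:
            ann["definition"] = str(comment)
        nodes[rid] = RegionNode(
            region_id=rid,
            display_name=str(label),
            parent_id=parent_id,
            segmentation_ids=sorted(
                int(v) for v in g.objects(cls, NP.segmentationId)),
            laterality=str(g.value(cls, NP.laterality)),
            tissue_class=str(g.value(cls, NP.tissueClass)),
            order_index=int(g.value(cls, NP.orderIndex)),
            struct_names=sorted(str(v)
                                for v in g.objects(cls, NP.structName)),
            annotations=ann,
        )
    if not nodes:
        raise OntologyError("document contains no atlas classes")

    parentless = [rid for rid, n in nodes.items() if n.parent_id is None]
    root_id = str(root_lit) if root_lit is not None else None
    if root_id is None:
        if len(parentless) != 1:
            raise OntologyError(
                f"cannot identify root: parentless classes {parentless}")
        root_id = parentless[0]
    if sorted(parentless) != [root_id]:
        raise OntologyError(
            f"classes without a parent link besides root {root_id!r}: "
            f"{sorted(set(parentless) - {root_id})}")

    for node in nodes.values():
        if node.parent_id is not None:
            if node.parent_id not in nodes:
                raise OntologyError(f"{node.region_id}: parent "
                                    f"{node.parent_id!r} not in document")
            nodes[node.parent_id].children_ids.append(node.region_id)
    for node in nodes.values():
        node.children_ids.sort(key=lambda c: nodes[c].order_index)

    from .atlas import _derive_measure_support
    _derive_measure_support(nodes, root_id)
    hierarchy = RegionHierarchy(
        nodes=nodes, root_id=root_id,
        name=str(atlas_name) if atlas_name is not None else "atlas")

    models: dict[tuple[str, str], NormativeModel] = {}
    for rid in hierarchy.traversal_order():
        cls = NP[rid]
        for measure in _MEASURES:
            sd = _opt(g, cls, NP[f"{measure}_residual_sd"])
            if sd is None:
                continue
            coefs = []
            for prop in _coef_props(measure):
                v = _opt(g, cls, prop)
                if v is None:
                    raise OntologyError(
                        f"class {rid}: has {measure} residual SD but is "
                        f"missing coefficient property {prop.n3(g.namespace_manager)}")
                coefs.append(float(v))
            n_train = _opt(g, cls, NP[f"{measure}_n_train"])
            models[(rid, measure)] = NormativeModel(
                region_id=rid, measure=measure, coefficients=coefs,
                residual_sd=float(sd),
                n_train=int(n_train) if n_train is not None else 7)
    model_set = NormativeModelSet(models=models) if models else None
    return hierarchy, model_set
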