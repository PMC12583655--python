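"""Hierarchical brain-anatomy model.

The pipeline quantifies regional pathology at two levels: the leaf regions
of interest (ROIs) produced by a DKT-protocol segmentation, and parent
concepts (lobes, hemispheres, whole brain) that aggregate them.  This module
defines the tree, validates it, and answers the traversal queries every
other stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

LATERALITIES = {"left", "right", "midline", "whole"}
TISSUE_CLASSES = {"cortical", "subcortical-gray", "white-matter",
                  "ventricular", "cerebellar", "brainstem", "other"}


class AtlasError(ValueError):
    """Malformed atlas definition or failed hierarchy invariant."""


class UnknownRegionError(KeyError):
    """Lookup of a region_id that is not in the hierarchy."""


@dataclass
class RegionNode:
    """A single anatomical concept (leaf ROI or aggregate parent).

    ``segmentation_ids`` carries the integer label codes of the segmentation
    lookup table and is non-empty exactly for leaves.  ``measure_support``
    lists which measures are meaningful for the node: every node supports
    ``volume``; ``thickness`` is supported by cortical leaves and by any
    parent with at least one cortical descendant.
    """

    region_id: str
    display_name: str
    parent_id: str | None
    children_ids: list[str] = field(default_factory=list)
    segmentation_ids: list[int] = field(default_factory=list)
    laterality: str = "midline"
    tissue_class: str = "other"
    order_index: int = 0
    measure_support: frozenset[str] = frozenset({"volume"})
    struct_names: list[str] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return bool(self.segmentation_ids)


@dataclass
class RegionHierarchy:
    """Validated tree of :class:`RegionNode` objects keyed by region_id."""

    nodes: dict[str, RegionNode]
    root_id: str
    name: str = "atlas"

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ---------------------------------------------------------
    def node(self, region_id: str) -> RegionNode:
        try:
            return self.nodes[region_id]
        except KeyError:
            raise UnknownRegionError(
                f"unknown region_id {region_id!r}") from None

    def ancestors(self, region_id: str) -> list[str]:
        """Region ids from the immediate parent up to (and including) root."""
        node = self.node(region_id)
        out: list[str] = []
        while node.parent_id is not None:
            out.append(node.parent_id)
            node = self.nodes[node.parent_id]
        return out

    def depth(self, region_id: str) -> int:
        return len(self.ancestors(region_id))

    def leaves_under(self, region_id: str) -> set[str]:
        """All leaf region_ids in the subtree rooted at ``region_id``."""
        node = self.node(region_id)
        if node.is_leaf:
            return {region_id}
        out: set[str] = set()
        for child in node.children_ids:
            out |= self.leaves_under(child)
        return out

    def descendants(self, region_id: str) -> set[str]:
        node = self.node(region_id)
        out: set[str] = set()
        for child in node.children_ids:
            out.add(child)
            out |= self.descendants(child)
        return out

    @property
    def leaf_ids(self) -> list[str]:
        return [r for r in self.traversal_order() if self.nodes[r].is_leaf]

    @property
    def parent_ids(self) -> list[str]:
        return [r for r in self.traversal_order()
                if not self.nodes[r].is_leaf]

    def traversal_order(self) -> list[str]:
        """Deterministic depth-first order (children by order_index)."""
        out: list[str] = []

        def walk(rid: str) -> None:
            out.append(rid)
            for c in self.nodes[rid].children_ids:
                walk(c)

        walk(self.root_id)
        return out

    def thickness_ids(self) -> list[str]:
        """Nodes supporting cortical thickness, in traversal order."""
        return [r for r in self.traversal_order()
                if "thickness" in self.nodes[r].measure_support]

    def cortical_leaves(self) -> list[str]:
        return [r for r in self.leaf_ids
                if self.nodes[r].tissue_class == "cortical"]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        roots = [r for r, n in self.nodes.items() if n.parent_id is None]
        if len(roots) != 1 or roots[0] != self.root_id:
            raise AtlasError(
                f"hierarchy must have exactly one root ({self.root_id}); "
                f"found parentless nodes {roots}")
        for rid, node in self.nodes.items():
            if node.region_id != rid:
                raise AtlasError(f"key {rid!r} != region_id "
                                 f"{node.region_id!r}")
            if node.is_leaf != (not node.children_ids):
                raise AtlasError(
                    f"{rid}: leaf status inconsistent (segmentation_ids "
                    f"non-empty iff children empty)")
            if node.parent_id is not None:
                parent = self.nodes.get(node.parent_id)
                if parent is None:
                    raise AtlasError(f"{rid}: parent {node.parent_id!r} "
                                     f"missing")
                if rid not in parent.children_ids:
                    raise AtlasError(f"{rid}: not listed among children of "
                                     f"{node.parent_id}")
            for c in node.children_ids:
                child = self.nodes.get(c)
                if child is None or child.parent_id != rid:
                    raise AtlasError(f"{rid}: child link {c!r} inconsistent")
            if node.laterality not in LATERALITIES:
                raise AtlasError(f"{rid}: bad laterality "
                                 f"{node.laterality!r}")
            if node.tissue_class not in TISSUE_CLASSES:
                raise AtlasError(f"{rid}: bad tissue_class "
                                 f"{node.tissue_class!r}")
        # acyclicity + connectivity: DFS from root must reach every node once
        seen = self.traversal_order()
        if len(seen) != len(self.nodes) or len(set(seen)) != len(seen):
            raise AtlasError("hierarchy is not a tree rooted at "
                             f"{self.root_id} (cycle or orphan detected)")
        # thickness only where a cortical descendant exists
        for rid, node in self.nodes.items():
            cortical = any(self.nodes[l].tissue_class == "cortical"
                           for l in self.leaves_under(rid))
            if ("thickness" in node.measure_support) != cortical:
                raise AtlasError(f"{rid}: thickness support must match "
                                 "presence of a cortical descendant")
        # left/right leaf-name symmetry at equal depth
        def swap(name: str) -> str:
            for a, b in (("Left", "Right"), ("lh_", "rh_"),
                         ("left_", "right_")):
                if a in name:
                    return name.replace(a, b)
                if b in name:
                    return name.replace(b, a)
            return name

        for side in ("left", "right"):
            for rid, node in self.nodes.items():
                if node.laterality != side:
                    continue
                mate = swap(rid)
                if mate not in self.nodes:
                    raise AtlasError(f"{rid}: no contralateral counterpart")
                if self.depth(mate) != self.depth(rid):
                    raise AtlasError(f"{rid}/{mate}: counterpart at "
                                     "different depth")

    def segmentation_lookup(self) -> dict[int, str]:
        """Map segmentation label code -> leaf region_id."""
        out: dict[int, str] = {}
        for rid in self.leaf_ids:
            for code in self.nodes[rid].segmentation_ids:
                out[code] = rid
        return out

    def struct_name_lookup(self) -> dict[str, str]:
        """Case-insensitive stats-file structure name -> leaf region_id."""
        out: dict[str, str] = {}
        for rid in self.leaf_ids:
            for name in self.nodes[rid].struct_names:
                out[name.lower()] = rid
        return out


def _derive_measure_support(nodes: dict[str, RegionNode],
                            root_id: str) -> None:
    def cortical_below(rid: str) -> bool:
        n = nodes[rid]
        if n.is_leaf:
            return n.tissue_class == "cortical"
        return any(cortical_below(c) for c in n.children_ids)

    for rid, n in nodes.items():
        support = {"volume"}
        if cortical_below(rid):
            support.add("thickness")
        n.measure_support = frozenset(support)


def load_atlas(path: str | Path) -> RegionHierarchy:
    """Load a hierarchy from a YAML atlas definition file."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    return _hierarchy_from_dict(raw)


def _hierarchy_from_dict(raw: dict) -> RegionHierarchy:
    if not isinstance(raw, dict) or "nodes" not in raw or "root_id" not in raw:
        raise AtlasError("atlas file must define 'root_id' and 'nodes'")
    nodes: dict[str, RegionNode] = {}
    for entry in raw["nodes"]:
        rid = entry["region_id"]
        if rid in nodes:
            raise AtlasError(f"duplicate region_id {rid!r}")
        ann = {}
        if "see_also" in entry:
            ann["seeAlso"] = entry["see_also"]
        if "definition" in entry:
            ann["definition"] = entry["definition"]
        nodes[rid] = RegionNode(
            region_id=rid,
            display_name=entry["display_name"],
            parent_id=entry.get("parent_id"),
            segmentation_ids=list(entry.get("segmentation_ids", [])),
            laterality=entry.get("laterality", "midline"),
            tissue_class=entry.get("tissue_class", "other"),
            order_index=int(entry.get("order_index", 0)),
            struct_names=list(entry.get("struct_names", [])),
            annotations=ann,
        )
    for rid, node in nodes.items():
        if node.parent_id is not None:
            if node.parent_id not in nodes:
                raise AtlasError(f"{rid}: parent {node.parent_id!r} missing")
            nodes[node.parent_id].children_ids.append(rid)
    for node in nodes.values():
        node.children_ids.sort(key=lambda c: nodes[c].order_index)
    _derive_measure_support(nodes, raw["root_id"])
    return RegionHierarchy(nodes=nodes, root_id=raw["root_id"],
                           name=raw.get("atlas_name", "atlas"))


def load_default_atlas() -> RegionHierarchy:
    """Load the bundled 100-leaf / 24-parent DKT-protocol hierarchy."""
    ref = resources.files("neuroprofile.data") / "atlas_dkt.yaml"
    with resources.as_file(ref) as path:
        return load_atlas(path)
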