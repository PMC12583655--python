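"""Hierarchical sunburst summary of a w-score profile.

Concentric rings mirror the anatomy tree: the whole brain at the center,
hemispheres/lobes on inner rings, leaf ROIs outermost.  The layout is fixed
and value-independent — every leaf gets the same angular width and the left
hemisphere's ordering is mirrored against the right — so plots from
different subjects are directly comparable at a glance.  Fill color encodes
the (fused) w-score with a diverging scale: yellow inside the "normal" band
|w| <= 1.5, ramping to saturated red for atrophy (negative w) and saturated
green for enlargement (positive w, e.g. ventricles), clamped beyond a
saturation cap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .atlas import RegionHierarchy
from .normative import WScoreProfile


class SunburstError(ValueError):
    pass


@dataclass(frozen=True)
class ColorScaleSpec:
    """Diverging w-score color scale (hue semantics fixed, anchors tunable)."""

    normal_halfwidth: float = 1.5     # |w| below this renders neutral
    significance: float = 2.0         # |w| above this is clearly pathological
    saturation_cap: float = 4.0       # |w| at which the ramp saturates
    neutral_hex: str = "#f7e967"      # yellow
    negative_hex: str = "#b2182b"     # red: atrophy
    positive_hex: str = "#1a9850"     # green: enlargement

    def __post_init__(self) -> None:
        if not 0 < self.normal_halfwidth < self.significance \
                < self.saturation_cap:
            raise SunburstError(
                "require 0 < normal_halfwidth < significance "
                "< saturation_cap")


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return tuple(int(h[i:i + 2], 16) for i in (0, 2, 4))


def _rgb_to_hex(rgb) -> str:
    return "#{:02x}{:02x}{:02x}".format(*(int(round(c)) for c in rgb))


def ramp_position(w: float, scale: ColorScaleSpec = ColorScaleSpec()
                  ) -> float:
    """Signed position in [-1, 1]: 0 inside the normal band, ±1 at the cap."""
    if not math.isfinite(w):
        raise SunburstError(f"non-finite w-score {w!r}")
    a = abs(w)
    if a <= scale.normal_halfwidth:
        return 0.0
    t = min((a - scale.normal_halfwidth)
            / (scale.saturation_cap - scale.normal_halfwidth), 1.0)
    return math.copysign(t, w)


def wscore_to_color(w: float,
                    scale: ColorScaleSpec = ColorScaleSpec()) -> str:
    """Continuous, |w|-monotone hex color for a w-score."""
    t = ramp_position(w, scale)
    if t == 0.0:
        return scale.neutral_hex
    target = scale.negative_hex if t < 0 else scale.positive_hex
    a = _hex_to_rgb(scale.neutral_hex)
    b = _hex_to_rgb(target)
    frac = abs(t)
    return _rgb_to_hex(tuple(a_i + frac * (b_i - a_i)
                             for a_i, b_i in zip(a, b)))


def fuse_measures(profile: WScoreProfile,
                  mode: str = "max_abs") -> dict[str, float]:
    """Per region, the single display w-score across measures.

    ``max_abs`` keeps the measure with the largest absolute deviation,
    sign preserved; single-measure regions pass through unchanged.
    """
    if mode != "max_abs":
        raise SunburstError(f"unknown fusion mode {mode!r}")
    fused: dict[str, float] = {}
    for (rid, _measure), w in profile.scores.items():
        if rid not in fused or abs(w) > abs(fused[rid]):
            fused[rid] = w
    return fused


@dataclass
class SunburstEntry:
    region_id: str
    label: str
    parent_id: str | None
    start_deg: float
    span_deg: float
    ring: int
    color: str
    hover: str
    initially_visible: bool = True


@dataclass
class SunburstSpec:
    entries: list[SunburstEntry]
    title: str = ""
    legend: dict = field(default_factory=dict)

    def geometry(self) -> list[tuple]:
        """Value-independent part: (region, parent, start, span, ring)."""
        return [(e.region_id, e.parent_id, e.start_deg, e.span_deg, e.ring)
                for e in self.entries]

    def to_json(self) -> str:
        return json.dumps({"title": self.title, "legend": self.legend,
                           "entries": [asdict(e) for e in self.entries]},
                          indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SunburstSpec":
        raw = json.loads(text)
        return cls(entries=[SunburstEntry(**e) for e in raw["entries"]],
                   title=raw.get("title", ""),
                   legend=raw.get("legend", {}))


def build_sunburst(profile: WScoreProfile, hierarchy: RegionHierarchy,
                   scale: ColorScaleSpec = ColorScaleSpec(),
                   fusion_mode: str = "max_abs",
                   max_depth: int | None = None,
                   title: str = "") -> SunburstSpec:
    """Lay out the hierarchy as a sunburst and color it by fused w-scores.

    Geometry depends only on the atlas: each leaf spans 360°/n_leaves and a
    parent spans the contiguous union of its leaves.  Children follow the
    atlas order index, reversed inside right-lateralized subtrees so
    homologous lobes face each other.  Rings deeper than ``max_depth`` are
    marked initially hidden (drill-down in the rendered artifact).
    """
    fused = fuse_measures(profile, fusion_mode)
    missing = [r for r in hierarchy.nodes if r not in fused]
    if missing:
        raise SunburstError(
            f"profile does not cover displayed regions {sorted(missing)[:5]}")

    n_leaves = len(hierarchy.leaf_ids)
    leaf_span = 360.0 / n_leaves
    entries: list[SunburstEntry] = []

    def hover_text(rid: str) -> str:
        node = hierarchy.nodes[rid]
        parts = [node.display_name]
        for measure in ("volume", "thickness"):
            key = (rid, measure)
            if key in profile.scores:
                s = f"w({measure}) = {profile.scores[key]:+.2f}"
                raw = profile.raw_values.get(key)
                if raw is not None:
                    unit = "mm³" if measure == "volume" else "mm"
                    s += f", {measure} = {raw:.1f} {unit}"
                parts.append(s)
        return " | ".join(parts)

    def walk(rid: str, start: float, depth: int) -> float:
        node = hierarchy.nodes[rid]
        n_under = len(hierarchy.leaves_under(rid))
        span = n_under * leaf_span
        entries.append(SunburstEntry(
            region_id=rid, label=node.display_name,
            parent_id=node.parent_id, start_deg=start, span_deg=span,
            ring=depth, color=wscore_to_color(fused[rid], scale),
            hover=hover_text(rid),
            initially_visible=(max_depth is None or depth <= max_depth)))
        children = list(node.children_ids)
        if node.laterality == "right":
            children = children[::-1]
        cursor = start
        for child in children:
            cursor = walk(child, cursor, depth + 1)
        return start + span

    walk(hierarchy.root_id, 0.0, 0)
    legend = {"normal_band": [-scale.normal_halfwidth,
                              scale.normal_halfwidth],
              "significance": scale.significance,
              "saturation_cap": scale.saturation_cap,
              "atrophy_hex": scale.negative_hex,
              "enlargement_hex": scale.positive_hex,
              "neutral_hex": scale.neutral_hex}
    return SunburstSpec(entries=entries,
                        title=title or f"w-score profile: "
                                       f"{profile.subject_id}",
                        legend=legend)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _arc_path(cx: float, cy: float, r0: float, r1: float,
              a0: float, a1: float) -> str:
    """SVG path for an annulus sector; angles in degrees, 12 o'clock = 0."""
    if a1 - a0 >= 360.0 - 1e-9:
        a1 = a0 + 359.999           # full ring: avoid degenerate arc
    rad0, rad1 = math.radians(a0 - 90), math.radians(a1 - 90)

    def pt(r: float, ang: float) -> str:
        return f"{cx + r * math.cos(ang):.3f},{cy + r * math.sin(ang):.3f}"

    large = 1 if (a1 - a0) > 180 else 0
    return (f"M {pt(r1, rad0)} A {r1:.3f} {r1:.3f} 0 {large} 1 "
            f"{pt(r1, rad1)} L {pt(r0, rad1)} "
            f"A {r0:.3f} {r0:.3f} 0 {large} 0 {pt(r0, rad0)} Z")


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
 body {{ font-family: sans-serif; }}
 path {{ stroke: #ffffff; stroke-width: 0.8; cursor: pointer; }}
 path:hover {{ opacity: 0.8; }}
 .legend {{ font-size: 12px; }}
</style></head>
<body>
<h2>{title}</h2>
<svg viewBox="0 0 {size} {size}" width="720" height="720">
{paths}
</svg>
<p class="legend">Yellow: |w| &le; {normal} (normal band) &mdash;
red ramp: atrophy (w &lt; 0) &mdash; green ramp: enlargement (w &gt; 0);
saturated at |w| = {cap}. Click a region to toggle its children.</p>
<script>
const spec = {spec_json};
function toggle(rid) {{
  for (const el of document.querySelectorAll('[data-parent="'+rid+'"]')) {{
    const hide = el.style.display !== 'none';
    el.style.display = hide ? 'none' : '';
    if (hide) hideBelow(el.getAttribute('data-region'));
  }}
}}
function hideBelow(rid) {{
  for (const el of document.querySelectorAll('[data-parent="'+rid+'"]')) {{
    el.style.display = 'none';
    hideBelow(el.getAttribute('data-region'));
  }}
}}
</script>
</body></html>
"""


def render_html(spec: SunburstSpec, path: str | Path) -> Path:
    """Write a self-contained interactive HTML file plus a JSON sidecar.

    The sidecar (same name, ``.json`` suffix) holds the exact
    :class:`SunburstSpec` for programmatic comparison and reload.
    """
    path = Path(path)
    size = 760.0
    cx = cy = size / 2
    max_ring = max(e.ring for e in spec.entries)
    ring_w = (size / 2 - 20.0) / (max_ring + 1)
    pieces = []
    for e in spec.entries:
        r0, r1 = e.ring * ring_w, (e.ring + 1) * ring_w
        if e.ring == 0:
            d = _arc_path(cx, cy, 0.0, r1, 0.0, 360.0)
        else:
            d = _arc_path(cx, cy, r0, r1, e.start_deg,
                          e.start_deg + e.span_deg)
        style = "" if e.initially_visible else ' style="display:none"'
        pieces.append(
            f'<path d="{d}" fill="{e.color}" data-region="{e.region_id}" '
            f'data-parent="{e.parent_id or ""}"{style} '
            f'onclick="toggle(\'{e.region_id}\')">'
            f'<title>{e.hover}</title></path>')
    html = _HTML_TEMPLATE.format(
        title=spec.title, size=f"{size:g}", paths="\n".join(pieces),
        normal=spec.legend.get("normal_band", [-1.5, 1.5])[1],
        cap=spec.legend.get("saturation_cap", 4.0),
        spec_json=spec.to_json())
    path.write_text(html)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(spec.to_json())
    return path
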