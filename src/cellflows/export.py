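"""Serialization of the graph + overlays to JSON and interactive HTML.

The on-disk form is a *visualization spec*: a versioned JSON document
holding node records (id, position, height, size, per-overlay colors,
hover content), link records (endpoints, count, proportions, per-overlay
colors), the ternary point set and an overlay registry.  The document is
written with a deterministic key order so export -> import -> export is
byte-identical, and a structural schema (shipped as
``viz-spec.schema.json``) is enforced before anything is written or
rendered.

The HTML export is a single self-contained file: the spec is embedded as
JSON and drawn as SVG by a small script, with an overlay selector and a
minimum-flow-proportion slider switching among the precomputed colorings.
No server or network access is involved.
"""

from __future__ import annotations

import json
import logging

import numpy as np

from .graph import SankeyGraph, layout_graph
from .overlays import NEUTRAL_HEX, TernaryPoint

_log = logging.getLogger("cellflows.export")

__all__ = [
    "SCHEMA_VERSION",
    "build_viz_spec",
    "validate_spec",
    "export_json",
    "import_json",
    "render_html",
    "write_paths_tsv",
]

SCHEMA_VERSION = "1.0"


def _json_scalar(v):
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    if isinstance(v, (np.ndarray, list, tuple)):
        return [_json_scalar(x) for x in v]
    if isinstance(v, dict):
        return {str(k): _json_scalar(x) for k, x in v.items()}
    if isinstance(v, np.bool_):
        return bool(v)
    return v


def build_viz_spec(
    g: SankeyGraph,
    ternary: list[TernaryPoint] | None = None,
    ternary_axes: list[str] | None = None,
    stable_paths=None,
) -> dict:
    """Assemble the serializable visualization spec from a laid-out graph.

    The overlay registry is derived from whatever paints and annotations
    are attached; node hover content collects metrics, annotations and
    marker tags.  Stable paths, when given, tag their member nodes.
    """
    if not g.layout:
        layout_graph(g)

    flow_overlays = sorted({name for f in g.flows for name in f.paint})
    node_overlays = sorted(
        {
            k
            for nd in g.nodes
            for k, v in nd.annotations.items()
            if isinstance(v, (int, float, np.integer, np.floating))
            and not isinstance(v, bool)
        }
    )

    path_of: dict[str, int] = {}
    for pi, p in enumerate(stable_paths or []):
        for nid in p.node_ids:
            path_of.setdefault(nid, pi)

    nodes = []
    for col in g.columns:
        for nd in col:
            pos = g.layout[nd.node_id]
            rec = {
                "id": nd.node_id,
                "resolution": nd.resolution_name,
                "label": nd.label,
                "size": nd.size,
                "x": pos["x"],
                "y": pos["y"],
                "height": pos["height"],
                "hover": {k: _json_scalar(v) for k, v in sorted(nd.annotations.items())},
            }
            if nd.node_id in path_of:
                rec["stable_path"] = path_of[nd.node_id]
            nodes.append(rec)

    links = [
        {
            "source": f.source,
            "target": f.target,
            "count": f.count,
            "forward_prop": f.forward_prop,
            "backward_prop": f.backward_prop,
            "paint": {name: _json_scalar(p) for name, p in sorted(f.paint.items())},
        }
        for f in g.flows
    ]
    points = [
        {
            "source": p.source,
            "target": p.target,
            "gep": [float(x) for x in p.gep.fractions],
            "count": p.count,
            "size": p.size,
            "color": p.color,
        }
        for p in (ternary or [])
    ]
    return {
        "schema_version": SCHEMA_VERSION,
        "n_cells": g.n_cells,
        "resolutions": list(g.resolution_names),
        "nodes": nodes,
        "links": links,
        "ternary": {"axes": list(ternary_axes or []), "points": points},
        "overlays": {
            "flow": flow_overlays,
            "node": node_overlays,
            "neutral": NEUTRAL_HEX,
        },
    }


# ---------------------------------------------------------------------------
# Validation (structural check implementing viz-spec.schema.json)
# ---------------------------------------------------------------------------

_NODE_REQUIRED = {
    "id": str,
    "resolution": str,
    "label": int,
    "size": int,
    "x": (int, float),
    "y": (int, float),
    "height": (int, float),
    "hover": dict,
}
_LINK_REQUIRED = {
    "source": str,
    "target": str,
    "count": int,
    "forward_prop": (int, float),
    "backward_prop": (int, float),
    "paint": dict,
}
_POINT_REQUIRED = {
    "source": str,
    "target": str,
    "gep": list,
    "count": int,
    "size": (int, float),
    "color": str,
}


def _require(record: dict, schema: dict, what: str) -> None:
    for key, typ in schema.items():
        if key not in record:
            raise ValueError(f"{what} record missing key {key!r}")
        if not isinstance(record[key], typ):
            raise ValueError(f"{what} key {key!r} has wrong type")


def validate_spec(spec: dict) -> None:
    """Structural validation of a visualization spec.

    Checks the schema version, record fields, that every link endpoint and
    ternary point refers to an existing node, and that every paint name a
    record carries is registered in the overlay registry.
    """
    for key in ("schema_version", "n_cells", "resolutions", "nodes", "links",
                "ternary", "overlays"):
        if key not in spec:
            raise ValueError(f"spec missing top-level key {key!r}")
    if spec["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {spec['schema_version']!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    node_ids = set()
    for rec in spec["nodes"]:
        _require(rec, _NODE_REQUIRED, "node")
        if rec["id"] in node_ids:
            raise ValueError(f"duplicate node id {rec['id']!r}")
        node_ids.add(rec["id"])
    registry = set(spec["overlays"].get("flow", []))
    for rec in spec["links"]:
        _require(rec, _LINK_REQUIRED, "link")
        for endpoint in (rec["source"], rec["target"]):
            if endpoint not in node_ids:
                raise ValueError(f"link endpoint {endpoint!r} is not a node")
        unknown = set(rec["paint"]) - registry
        if unknown:
            raise ValueError(f"link paint {sorted(unknown)} not in overlay registry")
    tern = spec["ternary"]
    if not isinstance(tern.get("axes"), list) or not isinstance(tern.get("points"), list):
        raise ValueError("ternary section must carry 'axes' and 'points' lists")
    for rec in tern["points"]:
        _require(rec, _POINT_REQUIRED, "ternary point")
        if rec["source"] not in node_ids or rec["target"] not in node_ids:
            raise ValueError("ternary point refers to an unknown node")


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------


def _dumps(spec: dict) -> str:
    # fixed separators + no key sorting (construction order is already
    # deterministic) => byte-stable output
    return json.dumps(spec, indent=1, sort_keys=False, allow_nan=False)


def export_json(spec: dict, path) -> None:
    """Validate and write a spec; deterministic byte output."""
    validate_spec(spec)
    text = _dumps(spec)
    with open(path, "w") as fh:
        fh.write(text + "\n")


def import_json(path) -> dict:
    """Read and validate a spec written by :func:`export_json`."""
    with open(path) as fh:
        spec = json.load(fh)
    validate_spec(spec)
    return spec


def write_paths_tsv(paths, cell_ids: list[str], out) -> None:
    """Stable paths as TSV: path id, span, node ids, stability, core size."""
    with open(out, "w") as fh:
        fh.write("path_id\tn_columns\tnode_ids\tstability\tcore_size\n")
        for i, p in enumerate(paths):
            fh.write(
                f"{i}\t{p.span}\t{','.join(p.node_ids)}\t"
                f"{p.stability:.6g}\t{p.core_size}\n"
            )


# ---------------------------------------------------------------------------
# HTML rendering
# ---------------------------------------------------------------------------

_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>cellflows: multi-resolution cluster flows</title>
<style>
body { font-family: sans-serif; margin: 1em; }
#controls { margin-bottom: 0.7em; }
.node rect { stroke: #333; stroke-width: 0.5; }
.flow { opacity: 0.65; }
.flow:hover { opacity: 0.95; }
text.nodelabel { font-size: 10px; }
#hover { font-size: 12px; white-space: pre; color: #222; min-height: 8em; }
svg { background: #fff; }
</style>
</head>
<body>
<h2>Multi-resolution cluster flows</h2>
<div id="controls">
  flow overlay:
  <select id="overlay"><option value="">(none)</option></select>
  &nbsp; min mutual proportion:
  <input id="minprop" type="range" min="0" max="1" step="0.01" value="0">
  <span id="minpropval">0.00</span>
</div>
<svg id="sankey" width="760" height="520"></svg>
<svg id="ternary" width="420" height="400"></svg>
<div id="hover"></div>
<script id="spec" type="application/json">__SPEC_JSON__</script>
<script>
var spec = JSON.parse(document.getElementById("spec").textContent);
var W = 700, H = 480, X0 = 40, Y0 = 20;
var nodeById = {};
spec.nodes.forEach(function (n) { nodeById[n.id] = n; });

var sel = document.getElementById("overlay");
spec.overlays.flow.forEach(function (name) {
  var o = document.createElement("option");
  o.value = name; o.textContent = name; sel.appendChild(o);
});

function flowColor(link, overlay) {
  if (!overlay || !(overlay in link.paint)) return "#999999";
  var p = link.paint[overlay];
  return p.hex || spec.overlays.neutral;
}

function draw() {
  var overlay = sel.value;
  var minprop = parseFloat(document.getElementById("minprop").value);
  document.getElementById("minpropval").textContent = minprop.toFixed(2);
  var svg = document.getElementById("sankey");
  while (svg.firstChild) svg.removeChild(svg.firstChild);
  var nw = 14;
  spec.links.forEach(function (l) {
    var mutual = Math.min(l.forward_prop, l.backward_prop);
    if (mutual < minprop) return;
    var s = nodeById[l.source], t = nodeById[l.target];
    var h = (l.count / spec.n_cells) * H;
    var x1 = X0 + s.x * W + nw, x2 = X0 + t.x * W;
    var y1 = Y0 + (s.y + s._off1) * H + h / 2, y2 = Y0 + (t.y + t._off2) * H + h / 2;
    s._off1 += l.count / spec.n_cells; t._off2 += l.count / spec.n_cells;
    var mx = (x1 + x2) / 2;
    var path = document.createElementNS("http://www.w3.org/2000/svg", "path");
    path.setAttribute("d", "M" + x1 + "," + y1 + " C" + mx + "," + y1 + " " +
                      mx + "," + y2 + " " + x2 + "," + y2);
    path.setAttribute("stroke", flowColor(l, overlay));
    path.setAttribute("stroke-width", Math.max(1, h));
    path.setAttribute("fill", "none");
    path.setAttribute("class", "flow");
    path.addEventListener("mouseover", function () {
      document.getElementById("hover").textContent =
        l.source + " -> " + l.target + "  cells: " + l.count +
        "  forward: " + l.forward_prop.toFixed(3) +
        "  backward: " + l.backward_prop.toFixed(3);
    });
    svg.appendChild(path);
  });
  spec.nodes.forEach(function (n) {
    n._off1 = 0; n._off2 = 0;
    var gEl = document.createElementNS("http://www.w3.org/2000/svg", "g");
    gEl.setAttribute("class", "node");
    var r = document.createElementNS("http://www.w3.org/2000/svg", "rect");
    r.setAttribute("x", X0 + n.x * W);
    r.setAttribute("y", Y0 + n.y * H);
    r.setAttribute("width", nw);
    r.setAttribute("height", Math.max(1, n.height * H));
    var fill = "#888888";
    if ("silhouette_normalized" in n.hover) {
      var v = n.hover.silhouette_normalized;
      var c = Math.round(255 * v);
      fill = "rgb(" + (255 - c) + "," + c + ",120)";
    }
    r.setAttribute("fill", fill);
    r.addEventListener("mouseover", function () {
      document.getElementById("hover").textContent =
        n.id + "  size: " + n.size + "\\n" + JSON.stringify(n.hover, null, 1);
    });
    gEl.appendChild(r);
    var t = document.createElementNS("http://www.w3.org/2000/svg", "text");
    t.setAttribute("x", X0 + n.x * W + nw + 2);
    t.setAttribute("y", Y0 + n.y * H + 9);
    t.setAttribute("class", "nodelabel");
    t.textContent = n.id;
    gEl.appendChild(t);
    svg.appendChild(gEl);
  });
  drawTernary();
}

function drawTernary() {
  var svg = document.getElementById("ternary");
  while (svg.firstChild) svg.removeChild(svg.firstChild);
  var cx = 210, top = 30, side = 340;
  var ax = cx - side / 2, ay = top + side * 0.866;
  var bx = cx + side / 2, by = ay, tx = cx, ty = top;
  var tri = document.createElementNS("http://www.w3.org/2000/svg", "path");
  tri.setAttribute("d", "M" + ax + "," + ay + " L" + bx + "," + by +
                   " L" + tx + "," + ty + " Z");
  tri.setAttribute("fill", "none"); tri.setAttribute("stroke", "#333");
  svg.appendChild(tri);
  var axes = spec.ternary.axes;
  [[ax - 10, ay + 14], [bx + 10, by + 14], [tx, ty - 8]].forEach(function (p, i) {
    if (!axes[i]) return;
    var t = document.createElementNS("http://www.w3.org/2000/svg", "text");
    t.setAttribute("x", p[0]); t.setAttribute("y", p[1]);
    t.setAttribute("text-anchor", "middle"); t.setAttribute("font-size", "11");
    t.textContent = axes[i];
    svg.appendChild(t);
  });
  spec.ternary.points.forEach(function (p) {
    var g1 = p.gep[0], g2 = p.gep[1], g3 = p.gep[2];
    var px = g1 * ax + g2 * bx + g3 * tx;
    var py = g1 * ay + g2 * by + g3 * ty;
    var c = document.createElementNS("http://www.w3.org/2000/svg", "circle");
    c.setAttribute("cx", px); c.setAttribute("cy", py);
    c.setAttribute("r", Math.max(1, p.size / 2));
    c.setAttribute("fill", p.color); c.setAttribute("fill-opacity", "0.75");
    c.addEventListener("mouseover", function () {
      document.getElementById("hover").textContent =
        "flow " + p.source + " -> " + p.target + "  cells: " + p.count +
        "  GEP: [" + p.gep.map(function (x) { return x.toFixed(3); }).join(", ") + "]";
    });
    svg.appendChild(c);
  });
}

sel.addEventListener("change", draw);
document.getElementById("minprop").addEventListener("input", draw);
draw();
</script>
</body>
</html>
"""


def render_html(spec: dict, out) -> None:
    """Write the spec as one self-contained interactive HTML document.

    The spec is validated first; two renders of the same spec produce
    identical files (no timestamps or randomness are embedded).
    """
    validate_spec(spec)
    html = _HTML_TEMPLATE.replace("__SPEC_JSON__", _dumps(spec).replace("</", "<\\/"))
    with open(out, "w") as fh:
        fh.write(html)
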