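"""Polygon annotation model and mask / XML / JSON interchange.

Annotations are named layers of class-labelled closed polygons with vertices
in base-resolution pixels. Three interchange forms are supported losslessly
(or as close as rasterization permits):

* integer label rasters at an arbitrary downsample (``rasterize`` /
  ``mask_to_annotations``),
* an ImageScope-compatible XML dialect
  (``Annotations/Annotation/Regions/Region/Vertices/Vertex``) with the
  per-region bounding box written as ``Region`` attributes so readers can
  skip regions outside a requested window,
* a versioned JSON schema for contour layers and sparse heatmaps.

Fill rule: a pixel is set when its center lies strictly inside the ring
(even-odd); with pixel centers at half-integer offsets this is deterministic
and reproducible by brute-force point-in-polygon. When polygons of different
classes overlap, later layers overwrite earlier ones (the layer order is the
precedence order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from lxml import etree
from skimage.measure import find_contours, label as cc_label

__all__ = [
    "Polygon",
    "AnnotationDocument",
    "HeatmapLayer",
    "rasterize",
    "mask_to_annotations",
    "read_aperio_xml",
    "write_aperio_xml",
    "to_json",
    "from_json",
    "AnnotationError",
    "SchemaError",
]

JSON_SCHEMA_VERSION = "1.0"


class AnnotationError(ValueError):
    """Malformed annotation input (XML or document structure)."""


class SchemaError(ValueError):
    """JSON does not conform to the annotation schema; carries the path."""

    def __init__(self, message, path="$"):
        super().__init__(f"{message} (at {path})")
        self.path = path


@dataclass
class Polygon:
    """Closed ring of >= 3 vertices in base-resolution pixels.

    The first vertex implicitly joins the last; ``bbox`` is always the
    vertex extrema ``(min_x, min_y, max_x, max_y)``.
    """

    vertices: np.ndarray
    class_label: str

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise AnnotationError("polygon needs an (N>=3, 2) vertex array")
        self.vertices = v

    @property
    def bbox(self):
        v = self.vertices
        return (
            float(v[:, 0].min()),
            float(v[:, 1].min()),
            float(v[:, 0].max()),
            float(v[:, 1].max()),
        )

    def to_shapely(self):
        return shapely.Polygon(self.vertices)

    def __eq__(self, other):
        return (
            isinstance(other, Polygon)
            and self.class_label == other.class_label
            and self.vertices.shape == other.vertices.shape
            and bool(np.all(self.vertices == other.vertices))
        )


@dataclass
class AnnotationDocument:
    """Ordered, named layers of polygons plus an optional class palette."""

    layers: dict = field(default_factory=dict)
    slide_id: str = "slide"
    palette: dict = field(default_factory=dict)
    heatmaps: list = field(default_factory=list)

    def __post_init__(self):
        for name, polys in self.layers.items():
            for p in polys:
                if p.class_label != name:
                    raise AnnotationError(
                        f"polygon class {p.class_label!r} does not match "
                        f"its layer {name!r}"
                    )

    def layer_names(self):
        return list(self.layers)

    def n_polygons(self):
        return sum(len(p) for p in self.layers.values())

    def add(self, polygon, layer=None):
        name = layer or polygon.class_label
        self.layers.setdefault(name, []).append(polygon)

    def __eq__(self, other):
        return (
            isinstance(other, AnnotationDocument)
            and self.slide_id == other.slide_id
            and list(self.layers) == list(other.layers)
            and all(
                len(self.layers[k]) == len(other.layers[k])
                and all(p == q for p, q in zip(self.layers[k], other.layers[k]))
                for k in self.layers
            )
        )


@dataclass
class HeatmapLayer:
    """Sparse per-class probability map.

    ``points`` is an (N, 3) array of ``(x, y, value)`` rows with coordinates
    already up-sampled to base resolution; ``scale_factor`` records the grid
    spacing the map was produced at. Values lie in [0, 1]; only entries at or
    above the sparsification threshold used at export time are stored.
    """

    points: np.ndarray
    class_label: str
    scale_factor: float = 1.0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if pts.size and (pts[:, 2].min() < 0 or pts[:, 2].max() > 1):
            raise AnnotationError("heatmap values must lie in [0, 1]")
        self.points = pts


# -- rasterization ----------------------------------------------------------


def _pixel_centers(origin, n, downsample):
    # pixel j at downsample d covers [origin + j*d, origin + (j+1)*d)
    return origin + (np.arange(n) + 0.5) * downsample


def rasterize(doc, region, downsample=1, class_map=None, layers=None):
    """Rasterize document polygons over a window into an integer label mask.

    Parameters
    ----------
    region : (x, y, w, h)
        Window in base-resolution pixels.
    downsample : float
        Output scale; the mask has shape ``(round(h / d), round(w / d))``.
    class_map : dict label -> int
        Integer written for each class; defaults to 1-based layer order.
        0 is reserved for unannotated background.
    layers : sequence of str, optional
        Subset of layers to draw, in document order. Unknown names raise.

    Only polygons whose bounding box intersects the window are considered
    (the bbox index); later layers overwrite earlier ones where classes
    overlap.
    """
    x0, y0, w, h = region
    d = float(downsample)
    out_w = int(round(w / d))
    out_h = int(round(h / d))
    names = list(doc.layers) if layers is None else list(layers)
    for name in names:
        if name not in doc.layers:
            raise AnnotationError(f"unknown layer {name!r}")
    if class_map is None:
        class_map = {name: i + 1 for i, name in enumerate(doc.layers)}
    missing = [n for n in names if n not in class_map]
    if missing:
        raise AnnotationError(f"class_map missing labels: {missing}")

    mask = np.zeros((out_h, out_w), dtype=np.int32)
    if out_w == 0 or out_h == 0:
        return mask
    xs = _pixel_centers(x0, out_w, d)
    ys = _pixel_centers(y0, out_h, d)
    for name in names:
        value = class_map[name]
        for poly in doc.layers[name]:
            bx0, by0, bx1, by1 = poly.bbox
            if bx1 < x0 or by1 < y0 or bx0 >= x0 + w or by0 >= y0 + h:
                continue  # bbox index: polygon cannot touch the window
            j0 = max(int(np.searchsorted(xs, bx0)), 0)
            j1 = min(int(np.searchsorted(xs, bx1, "right")), out_w)
            i0 = max(int(np.searchsorted(ys, by0)), 0)
            i1 = min(int(np.searchsorted(ys, by1, "right")), out_h)
            if j1 <= j0 or i1 <= i0:
                continue
            gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
            geom = poly.to_shapely()
            if not geom.is_valid:
                geom = geom.buffer(0)
            inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
            sub = mask[i0:i1, j0:j1]
            sub[inside.reshape(gy.shape)] = value
    return mask


def mask_to_annotations(mask, origin=(0, 0), scale=1.0, class_map=None,
                        slide_id="slide"):
    """Vectorize a label raster into one polygon per connected component.

    ``class_map`` maps class label -> integer value in the mask (the inverse
    direction of :func:`rasterize`); it defaults to ``class_<v>`` for every
    nonzero value present. Contours are traced at the 0.5 iso-level between
    foreground and background pixels, so rasterizing the result back at the
    same scale recovers the component up to boundary-pixel effects. Vertex
    coordinates are transformed to base resolution: multiplied by ``scale``
    and offset by ``origin``, with pixel index ``i`` mapped to center
    ``origin + (i + 0.5) * scale``.
    """
    mask = np.asarray(mask)
    values = sorted(int(v) for v in np.unique(mask) if v != 0)
    if class_map is None:
        class_map = {f"class_{v}": v for v in values}
    inv = {}
    for labelname, v in class_map.items():
        inv[int(v)] = labelname
    ox, oy = origin
    doc = AnnotationDocument(layers={}, slide_id=slide_id)
    for v in values:
        name = inv.get(v)
        if name is None:
            raise AnnotationError(f"mask value {v} missing from class_map")
        doc.layers.setdefault(name, [])
        comps = cc_label(mask == v, connectivity=2)
        for ci in range(1, comps.max() + 1):
            comp = comps == ci
            padded = np.pad(comp, 1).astype(np.float64)
            contours = find_contours(padded, 0.5)
            if not contours:
                continue
            ring = max(contours, key=len)  # outer boundary of the component
            rc = ring - 1.0  # undo padding; (row, col) at pixel indices
            verts = np.empty((len(rc), 2))
            verts[:, 0] = ox + (rc[:, 1] + 0.5) * scale
            verts[:, 1] = oy + (rc[:, 0] + 0.5) * scale
            if np.all(verts[0] == verts[-1]):
                verts = verts[:-1]
            if len(verts) < 3:
                continue
            doc.layers[name].append(Polygon(verts, name))
    return doc


# -- Aperio-style XML -------------------------------------------------------


def write_aperio_xml(doc, path):
    """Write the document in the ImageScope-compatible XML dialect.

    Layer order, labels and vertex coordinates survive a
    ``write -> read`` round trip exactly; per-region bounding boxes are
    stored as ``Region`` attributes for windowed readers.
    """
    root = etree.Element("Annotations")
    for aid, (name, polys) in enumerate(doc.layers.items(), start=1):
        ann = etree.SubElement(root, "Annotation", Id=str(aid), Name=name)
        color = doc.palette.get(name)
        if color is not None:
            ann.set("LineColor", str(int(color[0]) + 256 * int(color[1])
                                     + 65536 * int(color[2])))
        regions = etree.SubElement(ann, "Regions")
        for rid, poly in enumerate(polys, start=1):
            bx0, by0, bx1, by1 = poly.bbox
            region = etree.SubElement(
                regions,
                "Region",
                Id=str(rid),
                MinX=repr(bx0),
                MinY=repr(by0),
                MaxX=repr(bx1),
                MaxY=repr(by1),
            )
            vertices = etree.SubElement(region, "Vertices")
            for x, y in poly.vertices:
                etree.SubElement(vertices, "Vertex", X=repr(float(x)),
                                 Y=repr(float(y)))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="utf-8")


def read_aperio_xml(path, slide_id="slide"):
    """Parse the XML dialect written by :func:`write_aperio_xml`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AnnotationError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "Annotations":
        raise AnnotationError(
            f"expected <Annotations> root element, found <{root.tag}>"
        )
    doc = AnnotationDocument(layers={}, slide_id=slide_id)
    for ann in root.findall("Annotation"):
        name = ann.get("Name")
        if name is None:
            raise AnnotationError("<Annotation> element missing Name attribute")
        doc.layers.setdefault(name, [])
        lc = ann.get("LineColor")
        if lc is not None:
            n = int(lc)
            doc.palette[name] = (n % 256, (n // 256) % 256, (n // 65536) % 256)
        regions = ann.find("Regions")
        if regions is None:
            continue
        for region in regions.findall("Region"):
            vertices = region.find("Vertices")
            if vertices is None:
                raise AnnotationError("<Region> element missing <Vertices>")
            pts = []
            for vx in vertices.findall("Vertex"):
                if vx.get("X") is None or vx.get("Y") is None:
                    raise AnnotationError("<Vertex> element missing X/Y")
                pts.append((float(vx.get("X")), float(vx.get("Y"))))
            doc.layers[name].append(Polygon(np.array(pts), name))
    return doc


# -- JSON schema ------------------------------------------------------------


def to_json(obj, indent=None):
    """Serialize a document or a single heatmap layer to JSON text.

    Schema (version 1.0)::

        {"schema_version": "1.0", "slide_id": str,
         "palette": {label: [r, g, b]},
         "layers": [{"name": str,
                     "polygons": [{"points": [[x, y], ...]}]}],
         "heatmaps": [{"class": str, "scale_factor": float,
                       "points": [[x, y, value], ...]}]}

    Heatmap point coordinates are stored at base resolution (already
    up-sampled by the heatmap's scale factor).
    """
    if isinstance(obj, HeatmapLayer):
        doc = AnnotationDocument(layers={}, heatmaps=[obj])
    else:
        doc = obj
    payload = {
        "schema_version": JSON_SCHEMA_VERSION,
        "slide_id": doc.slide_id,
        "palette": {k: list(map(int, v)) for k, v in doc.palette.items()},
        "layers": [
            {
                "name": name,
                "polygons": [
                    {"points": [[float(x), float(y)] for x, y in p.vertices]}
                    for p in polys
                ],
            }
            for name, polys in doc.layers.items()
        ],
        "heatmaps": [
            {
                "class": hm.class_label,
                "scale_factor": float(hm.scale_factor),
                "points": [[float(x), float(y), float(v)]
                           for x, y, v in hm.points],
            }
            for hm in doc.heatmaps
        ],
    }
    return json.dumps(payload, indent=indent)


def _require(cond, message, path):
    if not cond:
        raise SchemaError(message, path)


def from_json(text, slide_id=None):
    """Parse annotation JSON back into an :class:`AnnotationDocument`.

    Raises :class:`SchemaError` naming the JSON path of the first violation.
    """
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON: {exc}") from exc
    _require(isinstance(payload, dict), "top level must be an object", "$")
    _require("layers" in payload, "missing required key 'layers'", "$")
    _require(isinstance(payload["layers"], list), "'layers' must be a list",
             "$.layers")
    doc = AnnotationDocument(
        layers={},
        slide_id=slide_id or payload.get("slide_id", "slide"),
        palette={k: tuple(v) for k, v in payload.get("palette", {}).items()},
    )
    for i, layer in enumerate(payload["layers"]):
        path = f"$.layers[{i}]"
        _require(isinstance(layer, dict), "layer must be an object", path)
        _require("name" in layer, "layer missing 'name'", path)
        name = layer["name"]
        doc.layers.setdefault(name, [])
        for j, poly in enumerate(layer.get("polygons", [])):
            ppath = f"{path}.polygons[{j}]"
            _require(isinstance(poly, dict) and "points" in poly,
                     "polygon missing 'points'", ppath)
            pts = poly["points"]
            _require(isinstance(pts, list) and len(pts) >= 3,
                     "polygon needs >= 3 points", f"{ppath}.points")
            for k, pt in enumerate(pts):
                _require(
                    isinstance(pt, list) and len(pt) == 2,
                    "point must be [x, y]", f"{ppath}.points[{k}]",
                )
            doc.layers[name].append(Polygon(np.array(pts, float), name))
    for i, hm in enumerate(payload.get("heatmaps", [])):
        path = f"$.heatmaps[{i}]"
        _require(isinstance(hm, dict) and "class" in hm,
                 "heatmap missing 'class'", path)
        pts = np.array(hm.get("points", []), dtype=np.float64).reshape(-1, 3)
        _require(
            pts.size == 0 or (pts[:, 2].min() >= 0 and pts[:, 2].max() <= 1),
            "heatmap values must lie in [0, 1]", f"{path}.points",
        )
        doc.heatmaps.append(
            HeatmapLayer(pts, hm["class"], float(hm.get("scale_factor", 1.0)))
        )
    return doc
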