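"""RSML (Root System Markup Language) 1.0 export and import.

One top-level ``<root>`` element holds the primary axis; each lateral is
a nested child ``<root>`` with its polyline geometry.  Coordinates are
written in cm (image frame, y downward).  Measured quantities that cannot
be recovered bit-exactly from re-digitised geometry — the primary
arclength and each lateral's insertion arclength and length — are stored
as RSML ``<properties>`` so a round trip reproduces every trait value.
"""

from __future__ import annotations

from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .architecture import Lateral, RootTopology, polyline_length

__all__ = ["export_rsml", "import_rsml"]

_FMT = "{:.8f}"


def _polyline_element(parent: ET.Element, polyline: np.ndarray) -> None:
    geom = ET.SubElement(parent, "geometry")
    poly = ET.SubElement(geom, "polyline")
    for x, y in np.asarray(polyline, dtype=float):
        ET.SubElement(poly, "point", x=_FMT.format(x), y=_FMT.format(y))


def _property_element(parent: ET.Element, name: str, value: float) -> None:
    props = parent.find("properties")
    if props is None:
        props = ET.SubElement(parent, "properties")
    ET.SubElement(props, name, value=_FMT.format(value))


def export_rsml(topology: RootTopology, path: str | Path,
                plant_label: str = "plant_1") -> None:
    """Write a topology as an RSML 1.0 document."""
    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "cm"
    ET.SubElement(meta, "resolution").text = "1"
    ET.SubElement(meta, "software").text = "rhizotrace"
    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", ID=plant_label, label=plant_label)

    primary = ET.SubElement(plant, "root", ID="primary", label="primary")
    _property_element(primary, "length_cm", topology.primary_length)
    _polyline_element(primary, topology.primary)

    for i, lat in enumerate(topology.laterals, start=1):
        child = ET.SubElement(primary, "root", ID=f"lateral_{i}", label="lateral")
        _property_element(child, "length_cm", lat.length)
        _property_element(child, "insertion_arclength_cm", lat.insertion_arclength)
        _polyline_element(child, lat.polyline)

    tree = ET.ElementTree(rsml)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def _read_polyline(root_el: ET.Element) -> np.ndarray:
    pts = [(float(p.get("x")), float(p.get("y")))
           for p in root_el.findall("./geometry/polyline/point")]
    return np.asarray(pts, dtype=float)


def _read_property(root_el: ET.Element, name: str) -> float | None:
    el = root_el.find(f"./properties/{name}")
    return float(el.get("value")) if el is not None else None


def _project_arclength(primary: np.ndarray, cum: np.ndarray,
                       point: np.ndarray) -> float:
    """Arclength along the primary of the point's orthogonal projection."""
    if len(primary) < 2:
        return 0.0
    best_d, best_s = np.inf, 0.0
    for i in range(len(primary) - 1):
        a, b = primary[i], primary[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((point - a) @ ab / denom, 0, 1))
        foot = a + t * ab
        d = float(np.hypot(*(point - foot)))
        if d < best_d:
            best_d = d
            best_s = float(cum[i]) + t * float(np.hypot(*ab))
    return best_s


def import_rsml(path: str | Path) -> RootTopology:
    """Read an RSML document back into a :class:`RootTopology`.

    Properties written by :func:`export_rsml` are used verbatim; RSML
    from other software falls back to recomputing lengths from the
    polylines and insertions from the nearest primary vertex.
    """
    tree = ET.parse(path)
    primary_el = tree.getroot().find("./scene/plant/root")
    if primary_el is None:
        raise ValueError("RSML document contains no root element")
    primary = _read_polyline(primary_el)
    primary_length = _read_property(primary_el, "length_cm")
    if primary_length is None:
        primary_length = polyline_length(primary)

    seg = np.sqrt(((primary[1:] - primary[:-1]) ** 2).sum(1)) if len(primary) > 1 else []
    cum = np.concatenate([[0.0], np.cumsum(seg)]) if len(primary) > 1 else np.zeros(1)

    laterals = []
    for child in primary_el.findall("root"):
        poly = _read_polyline(child)
        length = _read_property(child, "length_cm")
        if length is None:
            length = polyline_length(poly)
        insertion = _read_property(child, "insertion_arclength_cm")
        if insertion is None:
            insertion = _project_arclength(primary, cum, poly[0]) \
                * primary_length / max(float(cum[-1]), 1e-12)
        laterals.append(Lateral(
            insertion_arclength=insertion,
            insertion_from_apex=primary_length - insertion,
            polyline=poly,
            length=length,
        ))
    laterals.sort(key=lambda l: l.insertion_arclength)
    return RootTopology(primary=primary, laterals=laterals,
                        primary_length=primary_length)
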