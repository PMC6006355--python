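"""Per-reader nodule annotations and the XML dialect used to store them.

The on-disk format is a deliberately minimal LIDC-like schema::

    <LidcReadMessage patientId="P0001" shape="64,64,24" spacing="1,1,1">
      <readingSession>
        <servicingRadiologistID>reader-0</servicingRadiologistID>
        <unblindedReadNodule>
          <noduleID>N0</noduleID>
          <characteristics><malignancy>4</malignancy></characteristics>
          <roi>
            <imageZposition>7</imageZposition>
            <edgeMap><xCoord>12.5</xCoord><yCoord>30.5</yCoord></edgeMap>
            ...
          </roi>
        </unblindedReadNodule>
        <smallNodule><locus>...</locus></smallNodule>
        <nonNodule><locus>...</locus></nonNodule>
      </readingSession>
    </LidcReadMessage>

Readers mark regions in three classes.  Only "nodule >= 3 mm" regions carry
per-slice contours and a 1-5 malignancy rating; "nodule < 3 mm" and
"non-nodule" regions are noted by a single position in the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
from skimage.draw import polygon as _draw_polygon

NODULE_LARGE = "nodule >= 3 mm"
NODULE_SMALL = "nodule < 3 mm"
NON_NODULE = "non-nodule"

__all__ = [
    "NODULE_LARGE",
    "NODULE_SMALL",
    "NON_NODULE",
    "ReaderAnnotation",
    "mask_to_contours",
    "contours_to_mask",
    "read_annotations",
    "write_annotations",
]


# ---------------------------------------------------------------------------
# contour <-> mask conversion
# ---------------------------------------------------------------------------

def mask_to_contours(mask2d: np.ndarray) -> list[np.ndarray]:
    """Trace the boundary of a 2-D binary mask as closed polygons.

    The polygons run along pixel *edges* (vertices at half-integer
    coordinates), so rasterising them back with :func:`contours_to_mask`
    reproduces the mask exactly: no pixel centre ever lies on a polygon
    edge.  Holes and multiple components come back as separate rings;
    even-odd filling recovers the original set.

    Returns a list of ``(n, 2)`` float arrays of ``(x, y)`` vertices.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    padded = np.zeros((mask2d.shape[0] + 2, mask2d.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask2d

    # Directed crack edges, clockwise around each pixel (y grows "down").
    # Vertices stored at doubled integer coordinates to avoid float keys.
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    xs, ys = np.nonzero(mask2d)
    for x, y in zip(xs.tolist(), ys.tolist()):
        px, py = x + 1, y + 1
        if not padded[px, py - 1]:  # -y side
            a, b = (2 * x - 1, 2 * y - 1), (2 * x + 1, 2 * y - 1)
            edges.setdefault(a, []).append(b)
        if not padded[px + 1, py]:  # +x side
            a, b = (2 * x + 1, 2 * y - 1), (2 * x + 1, 2 * y + 1)
            edges.setdefault(a, []).append(b)
        if not padded[px, py + 1]:  # +y side
            a, b = (2 * x + 1, 2 * y + 1), (2 * x - 1, 2 * y + 1)
            edges.setdefault(a, []).append(b)
        if not padded[px - 1, py]:  # -x side
            a, b = (2 * x - 1, 2 * y + 1), (2 * x - 1, 2 * y - 1)
            edges.setdefault(a, []).append(b)

    rings: list[np.ndarray] = []
    while edges:
        start = next(iter(edges))
        ring = [start]
        cur = start
        while True:
            nxts = edges[cur]
            nxt = nxts.pop()
            if not nxts:
                del edges[cur]
            if nxt == start:
                break
            ring.append(nxt)
            cur = nxt
        rings.append(np.asarray(ring, dtype=float) / 2.0)
    return rings


def contours_to_mask(rings, shape) -> np.ndarray:
    """Rasterise closed ``(x, y)`` polygons into a 2-D mask (even-odd fill).

    Rings are filled individually and combined by XOR, which implements
    even-odd parity for nested rings (holes) and is exact for the
    edge-following rings produced by :func:`mask_to_contours`.
    """
    out = np.zeros(shape, dtype=bool)
    for ring in rings:
        ring = np.asarray(ring, dtype=float)
        if ring.shape[0] < 3:
            raise ValueError(
                f"contour with {ring.shape[0]} vertices: need at least 3"
            )
        rr, cc = _draw_polygon(ring[:, 0], ring[:, 1], shape=shape)
        out[rr, cc] ^= True
    return out


# ---------------------------------------------------------------------------
# annotation record
# ---------------------------------------------------------------------------

@dataclass
class ReaderAnnotation:
    """One reader's marking of one region of interest.

    ``slice_contours`` maps a z-slice index to the list of closed ``(x, y)``
    polygons the reader drew on that slice; it is present exactly when
    ``region_class`` is "nodule >= 3 mm", as is ``malignancy``.  The two
    point-only classes carry ``point`` instead.
    """

    reader_id: str
    region_class: str
    shape: tuple[int, int, int]
    slice_contours: dict[int, list[np.ndarray]] | None = None
    malignancy: int | None = None
    point: tuple[float, float, float] | None = None
    _mask: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.region_class not in (NODULE_LARGE, NODULE_SMALL, NON_NODULE):
            raise ValueError(f"unknown region class {self.region_class!r}")
        has_contours = bool(self.slice_contours)
        if self.region_class == NODULE_LARGE:
            if not has_contours:
                raise ValueError("'nodule >= 3 mm' annotations require contours")
            if self.malignancy is None or not 1 <= int(self.malignancy) <= 5:
                raise ValueError("'nodule >= 3 mm' annotations require malignancy 1-5")
        else:
            if has_contours:
                raise ValueError(
                    f"{self.region_class!r} regions are point-only, got contours"
                )
            if self.point is None:
                raise ValueError(f"{self.region_class!r} annotations require a point")

    @property
    def mask(self) -> np.ndarray:
        """3-D boolean mask rasterised from the per-slice contours."""
        if self.region_class != NODULE_LARGE:
            raise ValueError(f"{self.region_class!r} annotations carry no mask")
        if self._mask is None:
            m = np.zeros(self.shape, dtype=bool)
            for z, rings in self.slice_contours.items():
                m[:, :, z] = contours_to_mask(rings, self.shape[:2])
            self._mask = m
        return self._mask

    @property
    def slices(self) -> list[int]:
        return sorted(self.slice_contours) if self.slice_contours else []

    @classmethod
    def from_mask(
        cls,
        reader_id: str,
        mask: np.ndarray,
        malignancy: int,
    ) -> "ReaderAnnotation":
        """Build a contour annotation from an existing 3-D mask."""
        mask = np.asarray(mask, dtype=bool)
        contours = {
            int(z): mask_to_contours(mask[:, :, z])
            for z in np.nonzero(mask.any(axis=(0, 1)))[0]
        }
        ann = cls(
            reader_id=reader_id,
            region_class=NODULE_LARGE,
            shape=mask.shape,
            slice_contours=contours,
            malignancy=int(malignancy),
        )
        ann._mask = mask.copy()
        return ann


# ---------------------------------------------------------------------------
# XML I/O
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    return repr(float(value))


def write_annotations(
    path,
    patient_id: str,
    shape,
    spacing,
    sessions: dict[str, list[ReaderAnnotation]],
) -> Path:
    """Serialise one scan's reading sessions to the XML dialect.

    ``sessions`` maps reader id to that reader's annotations.
    """
    root = ET.Element(
        "LidcReadMessage",
        patientId=patient_id,
        shape=",".join(str(int(s)) for s in shape),
        spacing=",".join(_fmt(s) for s in spacing),
    )
    for reader_id, annotations in sessions.items():
        sess = ET.SubElement(root, "readingSession")
        ET.SubElement(sess, "servicingRadiologistID").text = reader_id
        for i, ann in enumerate(annotations):
            if ann.region_class == NODULE_LARGE:
                node = ET.SubElement(sess, "unblindedReadNodule")
                ET.SubElement(node, "noduleID").text = f"{reader_id}-N{i}"
                chars = ET.SubElement(node, "characteristics")
                ET.SubElement(chars, "malignancy").text = str(ann.malignancy)
                for z in ann.slices:
                    for ring in ann.slice_contours[z]:
                        roi = ET.SubElement(node, "roi")
                        ET.SubElement(roi, "imageZposition").text = str(int(z))
                        for x, y in ring:
                            em = ET.SubElement(roi, "edgeMap")
                            ET.SubElement(em, "xCoord").text = _fmt(x)
                            ET.SubElement(em, "yCoord").text = _fmt(y)
            else:
                tag = "smallNodule" if ann.region_class == NODULE_SMALL else "nonNodule"
                node = ET.SubElement(sess, tag)
                ET.SubElement(node, "noduleID").text = f"{reader_id}-N{i}"
                locus = ET.SubElement(node, "locus")
                x, y, z = ann.point
                ET.SubElement(locus, "xCoord").text = _fmt(x)
                ET.SubElement(locus, "yCoord").text = _fmt(y)
                ET.SubElement(locus, "imageZposition").text = _fmt(z)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    path = Path(path)
    tree.write(path, encoding="unicode", xml_declaration=True)
    return path


def read_annotations(xml_path) -> list[ReaderAnnotation]:
    """Parse one scan's XML annotation file into ReaderAnnotation records.

    Raises ``ValueError`` naming the offending element for malformed files
    or contours with fewer than 3 vertices.
    """
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed annotation XML {xml_path}: {exc}") from exc
    if root.tag != "LidcReadMessage":
        raise ValueError(f"unexpected root element <{root.tag}> in {xml_path}")
    shape = tuple(int(s) for s in root.attrib["shape"].split(","))

    annotations: list[ReaderAnnotation] = []
    for sess in root.iter("readingSession"):
        reader_id = sess.findtext("servicingRadiologistID", default="?")
        for node in sess.iter("unblindedReadNodule"):
            nid = node.findtext("noduleID", default="?")
            mal = node.findtext("characteristics/malignancy")
            if mal is None:
                raise ValueError(f"nodule {nid}: missing malignancy rating")
            contours: dict[int, list[np.ndarray]] = {}
            for roi in node.iter("roi"):
                z = int(float(roi.findtext("imageZposition")))
                verts = [
                    (float(em.findtext("xCoord")), float(em.findtext("yCoord")))
                    for em in roi.iter("edgeMap")
                ]
                if len(verts) < 3:
                    raise ValueError(
                        f"nodule {nid} roi at z={z}: contour has "
                        f"{len(verts)} vertices (need >= 3)"
                    )
                contours.setdefault(z, []).append(np.asarray(verts, dtype=float))
            if not contours:
                raise ValueError(f"nodule {nid}: no roi contours")
            annotations.append(
                ReaderAnnotation(
                    reader_id=reader_id,
                    region_class=NODULE_LARGE,
                    shape=shape,
                    slice_contours=contours,
                    malignancy=int(mal),
                )
            )
        for tag, region_class in (
            ("smallNodule", NODULE_SMALL),
            ("nonNodule", NON_NODULE),
        ):
            for node in sess.iter(tag):
                locus = node.find("locus")
                if locus is None:
                    raise ValueError(f"<{tag}> without <locus> in {xml_path}")
                point = (
                    float(locus.findtext("xCoord")),
                    float(locus.findtext("yCoord")),
                    float(locus.findtext("imageZposition")),
                )
                annotations.append(
                    ReaderAnnotation(
                        reader_id=reader_id,
                        region_class=region_class,
                        shape=shape,
                        point=point,
                    )
                )
    return annotations
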