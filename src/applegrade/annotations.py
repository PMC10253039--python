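"""Object-annotation readers/writers: PASCAL VOC XML and YOLO txt.

Boxes are pixel coordinates, origin top-left, half-open
``[x_min, x_max) x [y_min, y_max)``.  The YOLO dialect stores
``class_index cx cy w h`` normalized to the image size; the class vocabulary
must be supplied to map indices to names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

__all__ = ["BoxAnnotation", "write_voc_xml", "read_voc_xml", "write_yolo_txt", "read_yolo_txt"]

DETECTOR_CLASSES = ("stem_calyx", "defect")
GRADER_CLASSES = ("grade1", "grade2", "grade3")


@dataclass(frozen=True)
class BoxAnnotation:
    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def write_voc_xml(
    path: str | Path,
    image_name: str,
    width: int,
    height: int,
    boxes: list[BoxAnnotation],
    comment: str | None = None,
) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = image_name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(width)
    ET.SubElement(size, "height").text = str(height)
    ET.SubElement(size, "depth").text = "3"
    for box in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.label
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = f"{box.x_min:g}"
        ET.SubElement(bnd, "ymin").text = f"{box.y_min:g}"
        ET.SubElement(bnd, "xmax").text = f"{box.x_max:g}"
        ET.SubElement(bnd, "ymax").text = f"{box.y_max:g}"
    tree = ET.ElementTree(root)
    ET.indent(tree)
    path = Path(path)
    with path.open("wb") as fh:
        if comment:
            fh.write(f"<!-- {comment} -->\n".encode())
        tree.write(fh, encoding="utf-8")


def read_voc_xml(path: str | Path) -> tuple[str, int, int, list[BoxAnnotation]]:
    root = ET.parse(str(path)).getroot()
    name = root.findtext("filename", default="")
    width = int(root.findtext("size/width"))
    height = int(root.findtext("size/height"))
    boxes = [
        BoxAnnotation(
            label=obj.findtext("name"),
            x_min=float(obj.findtext("bndbox/xmin")),
            y_min=float(obj.findtext("bndbox/ymin")),
            x_max=float(obj.findtext("bndbox/xmax")),
            y_max=float(obj.findtext("bndbox/ymax")),
        )
        for obj in root.iter("object")
    ]
    return name, width, height, boxes


def write_yolo_txt(
    path: str | Path,
    width: int,
    height: int,
    boxes: list[BoxAnnotation],
    classes: tuple[str, ...] = DETECTOR_CLASSES,
) -> None:
    lines = []
    for box in boxes:
        idx = classes.index(box.label)
        cx = (box.x_min + box.x_max) / 2 / width
        cy = (box.y_min + box.y_max) / 2 / height
        w = (box.x_max - box.x_min) / width
        h = (box.y_max - box.y_min) / height
        lines.append(f"{idx} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(
    path: str | Path,
    width: int,
    height: int,
    classes: tuple[str, ...] = DETECTOR_CLASSES,
) -> list[BoxAnnotation]:
    boxes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        idx, cx, cy, w, h = line.split()
        cx, cy, w, h = float(cx) * width, float(cy) * height, float(w) * width, float(h) * height
        boxes.append(
            BoxAnnotation(
                label=classes[int(idx)],
                x_min=cx - w / 2,
                y_min=cy - h / 2,
                x_max=cx + w / 2,
                y_max=cy + h / 2,
            )
        )
    return boxes
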