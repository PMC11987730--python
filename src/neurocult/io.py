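"""Reading and writing frames, masks, detections and metrics.

Images are written as 16-bit single-channel TIFF or 8-bit PNG; ground
truth and frame summaries as JSON with all geometry in mm; detections
and traces as CSV in physical units.  CSV outputs carry a leading
comment line with the config hash and seed so runs are traceable; pandas
reads them back with ``comment='#'``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import MissingMetadataError, ValidationError
from .simulate import FrameScene, Soma, Dendrite
from .masking import SomaDetection, DendriteTrace

__all__ = [
    "write_image",
    "read_image",
    "write_truth",
    "read_truth",
    "detections_to_frame",
    "traces_to_frame",
    "write_csv",
]


def write_image(image: np.ndarray, path) -> None:
    """Write a grayscale image: .tif as uint16, .png as uint8."""
    path = Path(path)
    arr = np.asarray(image, dtype=np.float64)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.clip(arr, 0, 65535).round().astype(np.uint16))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, np.clip(arr, 0, 255).round().astype(np.uint8))
    else:
        raise ValidationError(f"unsupported image format {path.suffix!r}")


def read_image(path, pixel_size_um=None) -> tuple[np.ndarray, float]:
    """Read a grayscale image and its pixel size.

    The physical pixel size must be supplied (TIFF/PNG files from
    arbitrary sources carry no trustworthy scale); omitting it is a hard
    error, never a silent default.
    """
    if pixel_size_um is None:
        raise MissingMetadataError(
            "pixel_size_um is required to interpret the image physically")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2D grayscale image in {path}")
    return arr, float(pixel_size_um)


def write_truth(scene: FrameScene, path) -> None:
    """Ground truth as JSON: somata, dendrite polylines (mm), edges."""
    doc = {
        "pixel_size_um": scene.pixel_size_um,
        "somata": [
            {"id": s.id, "x_mm": s.x_mm, "y_mm": s.y_mm,
             "radius_mm": s.radius_mm, "clump_id": s.clump_id}
            for s in scene.somata
        ],
        "dendrites": [
            {"id": d.id, "polyline_mm": d.polyline_mm.tolist(),
             "width_mm": d.width_mm, "endpoints": list(d.endpoints)}
            for d in scene.dendrites
        ],
        "edges": [
            {"a": u, "b": v, "dendrite_id": k}
            for u, v, k in scene.true_graph.edges(keys=True)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_truth(path) -> FrameScene:
    """Reload ground truth written by :func:`write_truth` (no image)."""
    import networkx as nx

    doc = json.loads(Path(path).read_text())
    somata = [Soma(d["id"], d["x_mm"], d["y_mm"], d["radius_mm"],
                   d["clump_id"]) for d in doc["somata"]]
    dendrites = [Dendrite(d["id"], np.array(d["polyline_mm"]),
                          d["width_mm"], tuple(d["endpoints"]))
                 for d in doc["dendrites"]]
    g = nx.MultiGraph()
    g.add_nodes_from(s.id for s in somata)
    for e in doc["edges"]:
        g.add_edge(e["a"], e["b"], key=e["dendrite_id"])
    return FrameScene(somata=somata, dendrites=dendrites, true_graph=g,
                      image=None, pixel_size_um=doc["pixel_size_um"])


def detections_to_frame(detections: list[SomaDetection]) -> pd.DataFrame:
    return pd.DataFrame([
        {"id": d.id, "x_mm": d.x_mm, "y_mm": d.y_mm,
         "radius_mm": d.radius_mm, "circularity": d.circularity,
         "is_clump": d.is_clump,
         "estimated_cell_count": d.estimated_cell_count}
        for d in detections
    ], columns=["id", "x_mm", "y_mm", "radius_mm", "circularity",
                "is_clump", "estimated_cell_count"])


def traces_to_frame(traces: list[DendriteTrace]) -> pd.DataFrame:
    return pd.DataFrame([
        {"id": t.id, "length_mm": t.length_mm,
         "mean_width_mm": t.mean_width_mm,
         "n_attachments": len(t.attachments),
         "soma_a": t.attachments[0] if len(t.attachments) > 0 else "",
         "soma_b": t.attachments[1] if len(t.attachments) > 1 else ""}
        for t in traces
    ], columns=["id", "length_mm", "mean_width_mm", "n_attachments",
                "soma_a", "soma_b"])


def write_csv(df: pd.DataFrame, path, config_hash: str = "",
              seed=None, float_format: str = "%.10g") -> None:
    """Write a CSV with a traceability comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False, float_format=float_format)
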