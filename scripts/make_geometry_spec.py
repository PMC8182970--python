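"""Regenerate the shipped modified-M5 cross-section spec (data/m5_geometry.json).

The outline follows the M5 vocal-fold cross section in a hemilaryngeal mount:
x is medial-lateral (contact plane at large x), z inferior-superior with z = 0
at the glottal outlet.  Layer interfaces are inward offsets of the air-exposed
surface, so the soft cover layers wrap the inferior ramp, medial surface and
superior face while the body fills the core down to the fixed mount.
"""
from __future__ import annotations

import json
import pathlib

from shapely.geometry import LineString, Polygon

# Outline vertices (mm), counter-clockwise.  Lateral mount wall at x = 0,
# inferior mount face at z = -9.  Entrance ramp rises at ~49 deg from the
# mount to the glottal inlet (z = -3.6); the medial surface converges ~2.4 deg
# toward the contact plane at x = 8.4, reaching it at the outlet (z = 0).
OUTLINE = [
    (0.0, -9.0),
    (2.0, -9.0),
    (8.25, -3.6),
    (8.4, 0.0),
    (7.0, 1.0),
    (0.0, 1.0),
]

# Air-exposed surface polyline, inferior -> superior.
GAMMA_F = OUTLINE[1:]

# Inward offset distance (mm) from the air-exposed surface to each interface.
OFFSETS = {"SLP": 0.3, "ligament": 2.3, "body": 3.0}

CONTACT_PLANE_X = 8.4
DEPTH = 14.0  # anterior-posterior depth used for width <-> area conversion
CHANNEL = {"z_in": -3.6, "z_out": 0.0}


def build_spec() -> dict:
    outline = Polygon(OUTLINE)
    surface = LineString(GAMMA_F)
    interfaces = {}
    for name, d in OFFSETS.items():
        region = outline.difference(surface.buffer(d, quad_segs=8))
        if region.geom_type == "MultiPolygon":
            region = max(region.geoms, key=lambda g: g.area)
        region = region.simplify(0.02)
        coords = [(round(x, 4), round(z, 4)) for x, z in region.exterior.coords[:-1]]
        interfaces[name] = coords
    return {
        "name": "modified-M5 four-layer cross-section",
        "version": 1,
        "outline": [list(v) for v in OUTLINE],
        "interfaces": {k: [list(v) for v in c] for k, c in interfaces.items()},
        "contact_plane_x": CONTACT_PLANE_X,
        "depth": DEPTH,
        "channel": CHANNEL,
    }


if __name__ == "__main__":
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "vocalfem" / "data" / "m5_geometry.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(build_spec(), indent=1))
    print(f"wrote {out}")
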