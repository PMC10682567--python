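"""Range models and the proportional range-marginality statistic.

Builds a species range (coordinate-mean center + convex hull) from a point
cloud and evaluates marginality r = d_center / (d_center + d_margin) at the
center, at a hull vertex, and at an intermediate point.
"""

import json

import numpy as np

from exsertia import GeoPoint, build_range_model, marginality
from exsertia.geometry import range_model_to_geojson

rng = np.random.default_rng(7)
lon = rng.uniform(-85, -70, 200)
lat = rng.uniform(38, 46, 200)
model = build_range_model(list(zip(lon, lat)))
print(f"range model: center ({model.center.longitude:.3f}, "
      f"{model.center.latitude:.3f}), {len(model.hull)} hull vertices, "
      f"{model.n_points} points")

for label, point in (
    ("range center", model.center),
    ("hull vertex", model.hull[0]),
    ("midway point", GeoPoint((model.center.longitude + model.hull[0].longitude) / 2,
                              (model.center.latitude + model.hull[0].latitude) / 2)),
):
    res = marginality(point, model)
    print(f"{label:>13}: d_center = {res.d_center / 1000:8.1f} km, "
          f"d_margin = {res.d_margin / 1000:7.1f} km, r = {res.r:.3f}")

print("\nr runs from 0 at the range center to 1 on the range margin;")
print("distances are great-circle (haversine, sphere radius 6378137 m).")

geojson = range_model_to_geojson(model)
print(f"\nGeoJSON export: {len(geojson['features'])} features "
      f"({json.dumps(geojson['features'][1]['geometry'])})")
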