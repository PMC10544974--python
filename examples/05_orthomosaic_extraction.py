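"""Render an orthomosaic, mask soil, and extract plot means.

Writes a georeferenced GeoTIFF plus GeoJSON plot polygons, then recovers the
per-plot band values by pixel-center zonal statistics.
"""
from pathlib import Path

import numpy as np
import pandas as pd

import phenospectra as ps

rng = np.random.default_rng(21)
n = 12
vals = pd.DataFrame(
    {
        "plot_id": [f"p{i:02d}" for i in range(n)],
        "R680": rng.uniform(0.05, 0.12, n),
        "R800": rng.uniform(0.4, 0.6, n),
    }
)
raster, polys = ps.simulate_orthomosaic(vals, gsd=0.1, noise_sd=0.0)
out = Path("scratch_example")
out.mkdir(exist_ok=True)
raster.to_geotiff(out / "ortho.tif")
ps.write_geojson(polys, out / "plots.geojson")
print(f"rendered {raster.data.shape[0]}-band raster {raster.shape} at "
      f"{raster.pixel_size} m GSD with {len(polys)} plot polygons")

res = ps.mask_soil(raster, threshold=0.3, polygons=polys)
means = ps.extract_plot_means(raster, polys, mask=res.mask)
err = np.max(np.abs(means.set_index("plot_id")["R800"]
                    - vals.set_index("plot_id")["R800"]))
print(f"max |extracted - generated| over plots: {err:.2e} "
      "(exact on a noiseless mosaic)")
print(f"soil fraction masked across the scene: {res.mask.mean():.2f} — "
      "alleys and margins fall below the NDVI 0.3 threshold")
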