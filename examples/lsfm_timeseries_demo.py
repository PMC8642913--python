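"""Analyze a light-sheet microscopy time series from the command line.

Demonstration for real volumetric recordings (e.g. fused *Tribolium
castaneum* LSFM stacks; not bundled — pass your own multi-page TIFFs).
Large volumes become tractable by subsampling and skipping low-intensity
background windows, e.g.:

    volpiv piv recordings/ --out fields/ \
        --inter-size 20 --overlap 10 --multipass 2 --corr nsqecc \
        --subsample 3 --background-threshold 100 \
        --pitch 1.5 --interval 0.5

    volpiv postprocess fields/field_*.csv --out post/ \
        --ppr-threshold 1.2 --avg-radius 1 --avg-nt 1 \
        --maps velocity,divergence,collectiveness --trajectories 200

The same pipeline through the Python API:
"""

import sys
from pathlib import Path

from volpiv import PIVParams, VolumePair, io, run_piv, subsample_volume

if len(sys.argv) < 3:
    print(__doc__)
    print("usage: python lsfm_timeseries_demo.py frame_t.tif frame_t1.tif")
    sys.exit(0)

vt = subsample_volume(io.read_volume(sys.argv[1]), 3)
vt1 = subsample_volume(io.read_volume(sys.argv[2]), 3)
params = PIVParams(inter_size=20, overlap=10, mpass_factor=2,
                   corr_mode="nsqecc", background_threshold=100.0)
field = run_piv(VolumePair(vt, vt1), params)
out = Path("field_demo.vtk")
io.write_vector_field(field, out, format="vtk")
print(f"grid {field.grid_shape}, {(~field.background).sum()} foreground vectors, "
      f"wrote {out} (open in Paraview)")
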