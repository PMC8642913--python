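"""Quantify sub-pixel accuracy on fractional translations.

Sweeps fractional shifts of 0.1 .. 0.9 px on 2D synthetic particle images
and tabulates the bias error with and without the 3-point Gaussian
sub-pixel fit.  Without refinement the bias equals the distance to the
nearest integer (peak locking, up to 0.5 px); the Gaussian fit reduces it
by roughly an order of magnitude.
"""

from volpiv.synthetic import SweepAxis, SweepConfig, accuracy_sweep

shifts = [round(0.1 * i, 1) for i in range(1, 10)]
base = dict(domain_shape=(200, 200), inter_size=32, search_margin=4,
            density=0.05 * 32 * 32, n_particles=None, corr_mode="unnorm")

tables = {
    mode: accuracy_sweep(SweepAxis.FRACTIONAL_SHIFT, shifts,
                         SweepConfig(**base, subvoxel_mode=mode),
                         n_repeats=5, seed=11)
    for mode in ("none", "gaussian")
}

print("shift   bias (no sub-pixel)   bias (3-pt Gaussian)")
for s, b0, b1 in zip(shifts, tables["none"].bias_u, tables["gaussian"].bias_u):
    print(f" {s:.1f}        {b0:6.3f} px            {b1:6.4f} px")
gain = tables["none"].bias_u.mean() / tables["gaussian"].bias_u.mean()
print(f"mean-bias reduction from the Gaussian fit: {gain:.1f}x")
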