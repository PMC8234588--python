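"""Fit diffusion tensors and derive the scalar maps.

Simulates a noiseless subject, fits the tensor voxelwise by log-linear
least squares, and shows that FA, mean diffusivity and the Westin shape
measures come back at their designed values — the round trip that
validates the whole estimation chain.
"""

import numpy as np

import ichwm

layout = ichwm.PhantomLayout.small()
spec = ichwm.phantom_spec(layout, hematoma_volume_ml=3.0, noise_sigma=0.0)
field, gt = ichwm.generate_tensor_field(spec)
scheme = ichwm.default_scheme()
dwi = ichwm.simulate_dwi(field, scheme, ichwm.s0_map(spec, gt), 0.0)

maps = ichwm.compute_scalar_maps(dwi)   # FA, MD, cl, cp, cs + mean b0
fa, md = maps["FA"], maps["MD"]

err = np.nanmax(np.abs(fa.data - gt.true_fa_map))
print(f"max |fitted FA − true FA| over the volume: {err:.2e} (noiseless data)")

wm = gt.wm_mask
print(f"white matter:  FA {np.nanmean(fa.data[wm]):.3f}, "
      f"MD {np.nanmean(md.data[wm]) * 1e3:.2f} ×10⁻³ mm²/s "
      "(designed eigenvalues (1.7, 0.3, 0.3)×10⁻³ → FA 0.80, MD 0.77×10⁻³)")
bg = ~wm & ~gt.lesion_mask_true & ~gt.perilesional_shell_mask
print(f"background:    FA {np.nanmean(fa.data[bg]):.3f} (isotropic tissue → 0)")
print(f"hematoma core: FA {np.nanmean(fa.data[gt.lesion_mask_true]):.3f} "
      "(designed 0.15)")
cl = maps["cl"].data[wm]
print(f"Westin linear anisotropy in WM: {np.nanmean(cl):.3f} "
      "(cigar-shaped tensors are linear, not planar)")
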