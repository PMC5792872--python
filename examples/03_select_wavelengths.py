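"""Ordered predictor selection (OPS) of fat-informative wavelength regions.

Wavelengths are ranked by the magnitude of the PLS regression vector, nested
ranked subsets are scored by leave-one-out RMSECV, and the most parsimonious
subset within one standard error of the best is merged into contiguous
regions.  The selected regions should sit on the C-H fat bands the generator
placed near 1210, 1330, 1395, 1725 and 1762 nm.
"""

import nirtrace as nt
from nirtrace.ops import OPSConfig, run_ops
from nirtrace.preprocess import preset
from nirtrace.spectra import WavelengthRegions, make_split, restrict_to_regions

spectra = nt.generate(nt.default_study_profiles(), nt.default_generator_config(seed=0))
work = restrict_to_regions(spectra, WavelengthRegions([nt.WORKING_RANGE]))
cal, _ = make_split(work, "random_fraction", n_calibration=148, seed=0).apply(work)
cal_p = preset("SG17-SD").fit(cal).apply(cal)

result = run_ops(cal_p, OPSConfig())
print(f"kept {len(result.selected_indices)} of {cal_p.n_wavelengths} wavelengths "
      f"in {len(result.selected_regions)} regions:")
for lo, hi in result.selected_regions:
    print(f"  {lo:.0f}-{hi:.0f} nm")
print(f"RMSECV selected {result.rmsecv_selected:.3f} vs full set "
      f"{result.rmsecv_full:.3f} (fat-%)")
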