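"""Full PLS quantitation of total fat content.

148 calibration / 41 test random split; second-derivative preprocessing;
OPS wavelength selection; leave-one-out choice of the number of latent
variables; test-set prediction.  RMSEP is in fat-% and R^2 is the squared
Pearson correlation of predicted vs reference values.
"""

import nirtrace as nt
from nirtrace.ops import OPSConfig, run_ops
from nirtrace.pls import fit_pls, loo_cv, predict, score
from nirtrace.preprocess import preset
from nirtrace.spectra import WavelengthRegions, make_split, restrict_to_regions

spectra = nt.generate(nt.default_study_profiles(), nt.default_generator_config(seed=0))
work = restrict_to_regions(spectra, WavelengthRegions([nt.WORKING_RANGE]))
cal, test = make_split(work, "random_fraction", n_calibration=148, seed=0).apply(work)

pre = preset("SG17-SD").fit(cal)
cal_p, test_p = pre.apply(cal), pre.apply(test)

regions = run_ops(cal_p, OPSConfig()).selected_regions
cal_sel = restrict_to_regions(cal_p, regions)
test_sel = restrict_to_regions(test_p, regions)

loo = loo_cv(cal_sel)
model = fit_pls(cal_sel, loo.selected_l)
cal_score = score(predict(model, cal_sel), cal_sel.fat_pct)
test_score = score(predict(model, test_sel), test_sel.fat_pct)

print(f"latent variables l = {loo.selected_l} (LOO-selected), "
      f"RMSECV = {loo.rmsecv:.3f} fat-%")
print(f"calibration: R2 = {cal_score['r2']:.3f}")
print(f"test ({test_sel.n_samples} samples): RMSEP = {test_score['rmse']:.3f} fat-%, "
      f"R2 = {test_score['r2']:.3f}")
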