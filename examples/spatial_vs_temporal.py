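"""Spatial block cross-validation versus leave-one-year-out evaluation.

The same model family evaluated two ways: predicting unsampled locations
within sampled years (spatial) versus predicting a whole held-out year
(temporal). With soil measured once and only five annual precipitation
values, temporal transfer collapses while spatial transfer works.
"""

from commstack import (AbundancePipeline, ModelSpec, generate_dataset,
                       leave_one_year_out_eval, spatial_cv_eval)

table, _ = generate_dataset(seed=1)
proto = AbundancePipeline(
    kind="all_features",
    spec=ModelSpec("rf", n_estimators=80, max_samples=0.25, max_features=1.0))

spatial = spatial_cv_eval(table, proto.reseed, k=4, seed=1)
temporal = leave_one_year_out_eval(table, proto.reseed)

print("spatial 4-fold block CV, per-fold R^2:",
      [round(r.r2, 2) for r in spatial.records])
print(f"  median R^2 = {spatial.median_r2:.3f}")
print("leave-one-year-out, per-year R^2:")
for rec in temporal.records:
    print(f"  {rec.year}: R^2 = {rec.r2:6.2f}   RMSE = {rec.rmse:.1f}")
print(f"  median R^2 = {temporal.median_r2:.3f}")
print()
print("Negative yearly R^2 values mean the model is worse than predicting")
print("the mean: with one precipitation value per year, a held-out year's")
print("weather lies outside the training range and the year effect cannot")
print("be extrapolated. Spatial interpolation within known years is easy;")
print("temporal extrapolation from five years is not.")
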