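# Default per-group generator presets, calibrated to the published group
# summary statistics of the public gaitndd stride-interval database
# (ALS, PD, HD and healthy-control cohorts; 5-minute corridor walks).
# stride_mean_s / asymmetry / swing_fraction: group means of left stride
#   duration, left/right stride ratio, and swing as a fraction of stride.
# stride_sd_s: within-subject (detrended) stride SD; between_sd_s: spread
#   of subject means, chosen so that the pooled SD matches the published
#   group SD: between = sqrt(group_sd^2 - within^2).
# asymmetry_sd / cross_noise_s: between-subject spread of the ratio mean
#   and within-subject left-right noise, split 70/70 from the published
#   ratio SD (the true split is unreported; see docs/methods.md).
# ar1: lag-1 autocorrelation of stride fluctuations, decreasing from
#   controls to ALS to encode increasing stride-to-stride irregularity
#   (the published group ordering of entropy/complexity features).
group,stride_mean_s,stride_sd_s,between_sd_s,asymmetry,asymmetry_sd,cross_noise_s,swing_fraction,swing_noise_s,ar1,turn_rate,turn_scale,n_subjects
ALS,1.3911,0.065,0.19684,1.0177,0.02317,0.03224,0.32339,0.02,0.05,0.02,2.0,13
PD,1.1421,0.052,0.09762,1.0008,0.00217,0.00248,0.33284,0.02,0.75,0.02,2.0,15
HD,1.1605,0.120,0.11105,1.0003,0.00469,0.00544,0.34653,0.02,0.60,0.02,2.0,20
CTRL,1.0932,0.027,0.08449,0.9969,0.00105,0.00115,0.36029,0.02,0.88,0.02,2.0,16
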