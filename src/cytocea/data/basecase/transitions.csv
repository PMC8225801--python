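parameter,value,low,high,distribution,provenance
early_eac_mortality,0.0,,,beta,derived-calibration
early_to_late_eac,0.5233830795136872,,,beta,derived-calibration
esophagectomy_90day_mortality,0.04,,,beta,literature
hgd_to_early_eac,0.2367907794747985,,,beta,derived-calibration
hgd_to_lgd,0.0,,,beta,derived-calibration
late_eac_mortality,0.4000000000000001,,,beta,derived-calibration
lgd_to_hgd,0.07410619179199775,,,beta,derived-calibration
lgd_to_ndbe,0.03124552101349662,,,beta,derived-calibration
ndbe_to_early_eac,0.006486495460135128,,,beta,derived-calibration
ndbe_to_lgd,0.05357724642668657,,,beta,derived-calibration
nobe_to_ndbe,0.00010000000000000002,,,beta,derived-calibration
treat_success_early_eac,0.75,,,beta,literature
treat_success_hgd,0.85,,,beta,literature
treat_success_lgd,0.9,,,beta,literature
treat_success_ndbe,0.6133552823489046,,,beta,derived-calibration
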