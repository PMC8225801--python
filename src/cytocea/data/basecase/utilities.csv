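parameter,value,low,high,distribution,provenance
disutility_chemotherapy,0.15,,,beta,literature
disutility_emr_rfa,0.1,,,beta,literature
disutility_esophagectomy,0.2,,,beta,literature
disutility_perforation,0.15,,,beta,literature
disutility_stricture,0.12,,,beta,literature
duration_chemotherapy,0.375,,,fixed,trial-publication
duration_emr_rfa,0.07692307692307693,,,fixed,trial-publication
duration_esophagectomy,0.25,,,fixed,trial-publication
duration_perforation,0.07692307692307693,,,fixed,trial-publication
duration_stricture,0.038461538461538464,,,fixed,trial-publication
prob_perforation,0.01,,,beta,literature
prob_stricture,0.08,,,beta,literature
utility_earlyeac,0.67,,,beta:0.02,literature
utility_hgd,0.7013237503575382,,,beta:0.02,literature
utility_lateeac,0.45,,,beta:0.02,literature
utility_lgd,0.7213237503575383,,,beta:0.02,literature
utility_ndbe,0.7313237503575383,,,beta:0.02,derived-calibration
utility_nobe,0.7654221793230084,,,beta:0.02,derived-calibration
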