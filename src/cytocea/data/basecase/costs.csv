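parameter,value,low,high,distribution,provenance
chemotherapy,9000.0,,,gamma,literature
cytosponge_test,258.82224909310764,144.0,344.0,gamma,derived-calibration
endoscopy_biopsy,488.0,,,gamma,trial-publication
endotherapy_emr,2500.0,,,gamma,literature
endotherapy_rfa,2836.9154792112854,,,gamma,derived-calibration
esophagectomy,13000.0,,,gamma,literature
palliative_care,4000.0,,,gamma,literature
ppi_annual,6.542392536926364,,,gamma,derived-calibration
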