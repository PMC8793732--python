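specimen_id,element_label,centrum_length_cm,cotyle_height_cm,cotyle_width_cm
MB.R.2180,C4,45.7,13.8,
MB.R.2180,C6,69.1,15.0,22.1
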