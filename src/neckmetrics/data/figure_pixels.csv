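specimen_id,element_label,width_px,height_px,view,source
MB.R.2180,C4,683,722,posterior,photograph
MB.R.2180,C6,1190,820,posterior,photograph
CM 84,C13,264,256,posterior,plate
CM 84,C14,342,245,posterior,plate
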