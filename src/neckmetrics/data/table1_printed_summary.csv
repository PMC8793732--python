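specimen_id,max_diff,avg_diff,metric_diff_x100,max_ratio,avg_ratio,metric_ratio_x100,note
giraffe,0.151,0.062,6.201,1.208,1.086,8.636,
monitor,0.081,0.043,4.270,1.137,1.071,7.113,
alligator,0.121,0.055,5.546,1.159,1.070,6.986,
ostrich,0.092,0.063,6.298,1.135,1.089,8.903,
CM 84,0.243,0.091,9.130,1.361,1.120,11.955,max_ratio corrected from the source table's 1.139; its own 1st-ratio column contains 1.361 (C13 row) and the raw measurements give 1.361
MB.R.2180,0.378,0.163,16.288,1.568,1.221,22.100,
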