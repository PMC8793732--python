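specimen_id,element_label,vh,first_diff,first_ratio
giraffe,C2,0.685,0.086,1.126
giraffe,C3,0.771,0.014,1.018
giraffe,C4,0.785,0.014,1.018
giraffe,C5,0.771,0.045,1.062
giraffe,C6,0.726,0.151,1.208
giraffe,C7,0.878,,
monitor,C3,0.608,0.020,1.034
monitor,C4,0.588,0.007,1.012
monitor,C5,0.595,0.081,1.137
monitor,C6,0.676,0.062,1.102
monitor,C7,0.614,,
alligator,C5,0.931,0.060,1.068
alligator,C6,0.871,0.016,1.019
alligator,C7,0.888,0.121,1.159
alligator,C8,0.766,0.073,1.095
alligator,D1,0.839,0.007,1.008
alligator,D2,0.832,,
ostrich,C5,0.754,0.036,1.048
ostrich,C6,0.790,0.027,1.035
ostrich,C7,0.763,0.084,1.123
ostrich,C8,0.679,0.092,1.135
ostrich,C9,0.771,0.048,1.066
ostrich,C10,0.723,0.091,1.126
ostrich,C11,0.814,,
CM 84,C2,0.917,0.087,1.105
CM 84,C3,0.830,0.116,1.139
CM 84,C4,0.945,0.107,1.127
CM 84,C5,0.839,0.045,1.054
CM 84,C6,0.884,0.009,1.010
CM 84,C7,0.875,0.032,1.036
CM 84,C8,0.907,0.032,1.036
CM 84,C9,0.875,0.061,1.069
CM 84,C10,0.936,0.123,1.152
CM 84,C11,0.813,0.056,1.069
CM 84,C12,0.869,0.048,1.055
CM 84,C13,0.917,0.243,1.361
CM 84,C14,0.673,0.228,1.339
CM 84,C15,0.902,,
MB.R.2180,C2,1.205,0.180,1.176
MB.R.2180,C3,1.025,0.018,1.018
MB.R.2180,C4,1.043,0.378,1.568
MB.R.2180,C5,0.666,0.031,1.047
MB.R.2180,C6,0.697,0.207,1.297
MB.R.2180,C7,0.904,,
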