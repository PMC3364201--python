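rater_id,observed_delta,predicted_delta,fraction_explained,preferred_feature,slope
r00,0.75,0.13783,0.183773,size_px,0.000821787
r01,0.5,-0.0402801,-0.0805602,heterochromasia,0.123862
r02,0.375,-0.0712464,-0.18999,size_px,0.000773996
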