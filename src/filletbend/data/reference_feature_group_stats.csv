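# Previously reported sideview image-feature group means and standard
# deviations (pixel units except the unitless NMDM and MBE) for graded
# normal / moderate / severe wooden-breast fillets (n = 15 per group), with
# the Spearman correlation of each feature against the ordinal severity
# score. Used as transcription fixtures and to parameterize the simulator.
feature,normal_mean,normal_sd,moderate_mean,moderate_sd,severe_mean,severe_sd,spearman_rho
NMDM,0.41,0.10,0.63,0.05,0.66,0.08,0.75
MDM,41,11,63,5,67,7,0.77
MBE,35,20,9,5,7,7,-0.68
MAXH,73,8,80,7,85,7,0.51
AVGH,49,8,62,6,65,4,0.70
MAXL,319,12,322,18,323,15,0.10
AREA,16498,2628,19938,2553,21113,1784,0.67
PERIM,745,35,783,49,787,37,0.40
HTR,99,5,100,5,102,6,0.25
HBR,84,4,89,3,92,3,0.68
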