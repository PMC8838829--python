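# Previously reported SVM scores (10-repeated 5-fold CV averages; sideview
# features additionally averaged over the three line speeds) per feature and
# metric on the 45-fillet grading study. Cells only; the per-feature MEAN
# column is recomputed by the package.
feature,OACC,BACC,F1,MCC
NMDM,0.980,0.973,0.985,0.956
MDM,0.947,0.931,0.961,0.882
MBE,0.908,0.893,0.932,0.794
AvgThickness_mm,0.864,0.830,0.902,0.689
ShearEnergy_Nmm,0.851,0.843,0.886,0.673
AVGH,0.857,0.817,0.897,0.675
PeakShearForce_N,0.847,0.837,0.883,0.662
MaxThickness_mm,0.833,0.792,0.880,0.614
Weight_g,0.800,0.750,0.857,0.533
Volume_mm3,0.800,0.747,0.858,0.532
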