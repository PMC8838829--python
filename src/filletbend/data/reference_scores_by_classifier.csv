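# Previously reported mean cross-validation scores (10-repeated 5-fold CV,
# averaged over the four metrics and, for sideview features, over the three
# line speeds) for each single feature x classifier pair on the 45-fillet
# grading study. Cells only; marginal means are recomputed by the package.
feature,block,LDA,QDA,DT,SVM,KNN
NMDM,sideview,0.914,0.953,0.962,0.974,0.954
MDM,sideview,0.919,0.932,0.944,0.930,0.927
MBE,sideview,0.869,0.872,0.897,0.882,0.890
AVGH,sideview,0.819,0.810,0.752,0.812,0.780
AvgThickness_mm,instrument,0.839,0.855,0.798,0.821,0.836
ShearEnergy_Nmm,instrument,0.832,0.832,0.786,0.813,0.738
PeakShearForce_N,instrument,0.813,0.804,0.741,0.807,0.740
MaxThickness_mm,instrument,0.774,0.767,0.689,0.780,0.690
Volume_mm3,instrument,0.761,0.759,0.599,0.734,0.642
Weight_g,instrument,0.733,0.730,0.597,0.735,0.665
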