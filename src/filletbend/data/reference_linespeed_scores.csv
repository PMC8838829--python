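# Previously reported sideview-feature scores per metric and conveyor line
# speed (feet per minute), 10-repeated 5-fold CV averages on the 45-fillet
# grading study. Cells only; per-speed MEAN rows are recomputed.
feature,metric,fpm,score
MDM,OACC,10,0.960
MDM,OACC,50,0.948
MDM,OACC,100,0.932
NMDM,OACC,10,0.998
NMDM,OACC,50,0.995
NMDM,OACC,100,0.948
MBE,OACC,10,0.947
MBE,OACC,50,0.936
MBE,OACC,100,0.841
MDM,BACC,10,0.957
MDM,BACC,50,0.938
MDM,BACC,100,0.900
NMDM,BACC,10,0.997
NMDM,BACC,50,0.993
NMDM,BACC,100,0.930
MBE,BACC,10,0.943
MBE,BACC,50,0.939
MBE,BACC,100,0.796
MDM,F1,10,0.970
MDM,F1,50,0.961
MDM,F1,100,0.951
NMDM,F1,10,0.998
NMDM,F1,50,0.997
NMDM,F1,100,0.961
MBE,F1,10,0.960
MBE,F1,50,0.951
MBE,F1,100,0.886
MDM,MCC,10,0.910
MDM,MCC,50,0.884
MDM,MCC,100,0.851
NMDM,MCC,10,0.995
NMDM,MCC,50,0.990
NMDM,MCC,100,0.884
MBE,MCC,10,0.881
MBE,MCC,50,0.863
MBE,MCC,100,0.636
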