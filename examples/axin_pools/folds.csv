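condition,analyte,percents,fold
AXIN2-/-,AXIN1,161.9;214.9,
siAXIN2,AXIN2,28.7,
siAXIN2,AXIN1,163.2,
+/+ #1 G007-LK,AXIN2,615.4,
+/+ #1 G007-LK,AXIN1,194.2,
+/+ #2 ut,AXIN2,141.2,
+/+ #2 ut,AXIN1,67.9,
+/+ #2 G007-LK,AXIN2,1353.8,
+/+ #2 G007-LK,AXIN1,179.9,
AXIN2-/- #1 ut,AXIN1,175.7,
AXIN2-/- #1 G007-LK,AXIN1,198.3,
AXIN2-/- #2 ut,AXIN1,226.9,
AXIN2-/- #2 G007-LK,AXIN1,218.4,
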