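# Pool-composition run from published per-condition percent levels.
# The AXIN1:AXIN2 ratio of the untreated reference is fixed (bridging
# was run separately over six independent experiments), and every other
# condition is scaled by its analyte fold changes relative to that WT.
reference_condition: SW480
rounding: table
ratio: 3.56
output_dir: out
inputs:
  folds: folds.csv
conditions:
  - name: SW480
    reference: true
  - name: "AXIN2-/-"
    axin2_absent: true
  - name: siAXIN2
  - name: "+/+ #1 ut"
    reference: true
  - name: "+/+ #1 G007-LK"
  - name: "+/+ #2 ut"
  - name: "+/+ #2 G007-LK"
  - name: "AXIN2-/- #1 ut"
    axin2_absent: true
  - name: "AXIN2-/- #1 G007-LK"
    axin2_absent: true
  - name: "AXIN2-/- #2 ut"
    axin2_absent: true
  - name: "AXIN2-/- #2 G007-LK"
    axin2_absent: true
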