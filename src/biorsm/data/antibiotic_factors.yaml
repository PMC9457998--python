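# Factor ranges of the bundled antibiotic-digestion Box-Behnken study:
# pH, organic loading rate and dosed antibiotic concentration, each at
# three symmetric levels (coded -1 / 0 / +1).
factors:
  - name: pH
    low: 6.0
    high: 8.0
    units: ""
  - name: OLR
    low: 2.0
    high: 6.0
    units: "kgCOD.m-3.day-1"
  - name: ANT
    low: 10.0
    high: 100.0
    units: "%"
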