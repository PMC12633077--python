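# Plasma-choline rhythm scenario: ground truth taken from the published
# cosinor parameters for circulating choline in wild-type mice
# (MESOR 36.34, amplitude 43.346, acrophase ZT15.649, 24-h period).
# Noise sd defaults to amplitude/4 when omitted.
period_h: 24
timepoints: [2, 6, 10, 14, 18, 22]
n_per_cell: 8
features:
  - name: plasma_choline
    groups:
      wt: {mesor: 36.34, amplitude: 43.346, acrophase_h: 15.649}
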