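# Synthetic oscillating gut community: one rhythmic genus (peak ZT19)
# against flat companions; the knockout group carries the same oscillator
# shifted 12 h. Counts are Dirichlet-multinomial at lognormal library sizes.
taxa: [Blautia, Bacteroides, Dubosiella, Odoribacter, Alistipes]
baseline: [0.30, 0.25, 0.20, 0.15, 0.10]
amplitude: [0.06, 0.0, 0.0, 0.0, 0.0]
acrophase_h: [19.0, 0.0, 0.0, 0.0, 0.0]
lineages:
  - Bacteria;Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Blautia
  - Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides
  - Bacteria;Bacillota;Bacilli;Erysipelotrichales;Erysipelotrichaceae;Dubosiella
  - Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Marinifilaceae;Odoribacter
  - Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Rikenellaceae;Alistipes
concentration: 300
library_median: 20000
library_sigma: 0.25
groups: [wt, ko]
n_per_cell: 4
group_overrides:
  ko:
    Blautia: [0.06, 7.0]
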