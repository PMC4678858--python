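# Synthetic replication scenarios for the eight O4-alkyldT lesions and the
# lesion-free control.  Mixing ratios are the experimental design values
# (control 1:1; Me/Et/nPr/nBu 2:1; iPr/iBu/(S)-sBu/(R)-sBu 5:1 lesion genome
# to competitor genome).  `bypass` and `spectrum` are ground-truth parameters
# for the generator, chosen to emulate the reported magnitudes: near-complete
# bypass for all lesions except the two sBu diastereomers (~5%), exclusively
# T->C miscoding, with T->C frequency rising from ~40% (Me) to ~80% (Et/nPr)
# and near-100% for the branched/larger alkyl groups.  spectrum = [f_T, f_C,
# f_A, f_G].  sigma is the per-band lognormal noise (log-scale SD) and
# replicates the number of independent replication experiments.
control:
  bypass: 1.0
  spectrum: [1.0, 0.0, 0.0, 0.0]
  r_lesion: 1.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
Me:
  bypass: 0.85
  spectrum: [0.60, 0.40, 0.0, 0.0]
  r_lesion: 2.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
Et:
  bypass: 0.90
  spectrum: [0.20, 0.80, 0.0, 0.0]
  r_lesion: 2.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
nPr:
  bypass: 0.90
  spectrum: [0.20, 0.80, 0.0, 0.0]
  r_lesion: 2.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
iPr:
  bypass: 0.80
  spectrum: [0.03, 0.97, 0.0, 0.0]
  r_lesion: 5.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
nBu:
  bypass: 0.85
  spectrum: [0.03, 0.97, 0.0, 0.0]
  r_lesion: 2.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
iBu:
  bypass: 0.80
  spectrum: [0.03, 0.97, 0.0, 0.0]
  r_lesion: 5.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
sBu_S:
  bypass: 0.05
  spectrum: [0.03, 0.97, 0.0, 0.0]
  r_lesion: 5.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
sBu_R:
  bypass: 0.05
  spectrum: [0.03, 0.97, 0.0, 0.0]
  r_lesion: 5.0
  r_control: 1.0
  replicates: 3
  sigma: 0.1
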