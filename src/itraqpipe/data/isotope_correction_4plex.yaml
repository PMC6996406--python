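# iTRAQ 4-plex isotope impurity table (percent of each tag's reporter signal
# observed at -2/-1/+1/+2 channels away from its own).
#
# PLACEHOLDER VALUES: these are typical certificate-of-analysis figures for
# the 4-plex reagent family; the true factors vary per reagent lot.  Replace
# with the certificate shipped with the kit lot actually used.
impurity_percent:
  114: {-2: 0.0, -1: 1.0, 1: 5.9, 2: 0.2}
  115: {-2: 0.0, -1: 2.0, 1: 5.6, 2: 0.1}
  116: {-2: 0.0, -1: 3.0, 1: 4.5, 2: 0.1}
  117: {-2: 0.1, -1: 4.0, 1: 3.5, 2: 0.1}
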