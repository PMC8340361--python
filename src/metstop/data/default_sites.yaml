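# Default consensus membrane-binding site windows, as 1-based inclusive
# alignment columns on a ~140-column PX superfamily alignment:
#   site1 - membrane-insertion loop between strands beta1 and beta2
#   site2 - beta3 strand into helix alpha1 (PIP-coordinating RRY motif)
#   site3 - loop holding the proline-rich element, into helix alpha2
# These boundaries are a reconstruction from the consensus docking-site
# description; override per alignment with your own YAML of the same shape.
sites:
  site1: [30, 45]
  site2: [57, 75]
  site3: [95, 117]
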