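# Group x condition preset table, version 1.
#
# Multipliers are applied to a baseline synthesis configuration:
#   coupling         — scales the whole oscillator coupling matrix (rad/s)
#   rate             — scales every unit's mean firing rate (spikes/s)
#   evoked_coupling  — coupling scale inside the 500 ms post-stimulus epochs
#
# Directions encoded: chronic-pain (CCI) rest synchrony above control (CR)
# rest; tactile stimulation raises synchrony during evoked epochs; REAC
# application raises firing rates by the observed factors (1.43 / 1.93 /
# 1.09 / 1.41) and raises overall synchrony.  The synchrony multipliers are
# calibration choices (only directions are constrained), the REAC rate
# multipliers are the observed percent changes.
version: 1
presets:
  CR:
    rest:         {coupling: 1.0,  rate: 1.0,  evoked_coupling: 1.0}
    tactile:      {coupling: 1.0,  rate: 1.0,  evoked_coupling: 1.4}
    reac_rest:    {coupling: 1.3,  rate: 1.43, evoked_coupling: 1.3}
    reac_tactile: {coupling: 1.3,  rate: 1.09, evoked_coupling: 1.82}
  CCI:
    rest:         {coupling: 1.5,  rate: 1.0,  evoked_coupling: 1.5}
    tactile:      {coupling: 1.5,  rate: 1.0,  evoked_coupling: 2.1}
    reac_rest:    {coupling: 1.95, rate: 1.93, evoked_coupling: 1.95}
    reac_tactile: {coupling: 1.95, rate: 1.41, evoked_coupling: 2.73}
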