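# Local specifications for the calcium-handling toy models: the ER calcium
# reservoir should be able to stay full with the SERCA pump off, as long as
# the IP3R1 channel is closed; channel opening must empty it.
suite:
  name: calcium-module
  model: calcium_corrected
  cases:
    - name: rest_reservoir_full_without_pump
      context: {IP3R_stim: 0}
      oracle: stable_states
      quantifier: exists
      expect: {Calcium_ER: active, SERCA: inactive, IP3R1: inactive}
    - name: channel_open_empties_reservoir
      context: {IP3R_stim: 1}
      oracle: stable_states
      quantifier: all
      expect: {IP3R1: active, Calcium_ER: inactive}
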