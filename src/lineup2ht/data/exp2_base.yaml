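# Base model for the four-condition 2 (size: 2 vs 5) x 2 (format) lineup study:
# condition-specific dP and g, shared b and dA. Sampling constants 1/2 and 1/5
# are exact.
conditions:
  - {label: seq2, lineup_format: sequential, lineup_size: 2, sampling_constant: 0.5, n_participants: 408}
  - {label: seq5, lineup_format: sequential, lineup_size: 5, sampling_constant: 0.2, n_participants: 401}
  - {label: sim2, lineup_format: simultaneous, lineup_size: 2, sampling_constant: 0.5, n_participants: 393}
  - {label: sim5, lineup_format: simultaneous, lineup_size: 5, sampling_constant: 0.2, n_participants: 394}
restrictions:
  dP: {seq2: dP_seq2, seq5: dP_seq5, sim2: dP_sim2, sim5: dP_sim5}
  dA: {seq2: dA, seq5: dA, sim2: dA, sim5: dA}
  b: {seq2: b, seq5: b, sim2: b, sim5: b}
  g: {seq2: g_seq2, seq5: g_seq5, sim2: g_sim2, sim5: g_sim5}
free_parameters: [dP_seq2, dP_seq5, dP_sim2, dP_sim5, g_seq2, g_seq5, g_sim2, g_sim5, b, dA]
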