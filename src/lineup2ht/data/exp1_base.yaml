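# Base model for the four-condition 2 (size: 3 vs 6) x 2 (format) lineup study:
# condition-specific dP and g, a single b and a single dA shared by all
# conditions. Sampling constants use the study's 5-decimal roundings.
conditions:
  - {label: seq3, lineup_format: sequential, lineup_size: 3, sampling_constant: 0.33333, n_participants: 382}
  - {label: seq6, lineup_format: sequential, lineup_size: 6, sampling_constant: 0.16667, n_participants: 393}
  - {label: sim3, lineup_format: simultaneous, lineup_size: 3, sampling_constant: 0.33333, n_participants: 380}
  - {label: sim6, lineup_format: simultaneous, lineup_size: 6, sampling_constant: 0.16667, n_participants: 382}
restrictions:
  dP: {seq3: dP_seq3, seq6: dP_seq6, sim3: dP_sim3, sim6: dP_sim6}
  dA: {seq3: dA, seq6: dA, sim3: dA, sim6: dA}
  b: {seq3: b, seq6: b, sim3: b, sim6: b}
  g: {seq3: g_seq3, seq6: g_seq6, sim3: g_sim3, sim6: g_sim6}
free_parameters: [dP_seq3, dP_seq6, dP_sim3, dP_sim6, g_seq3, g_seq6, g_sim3, g_sim6, b, dA]
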