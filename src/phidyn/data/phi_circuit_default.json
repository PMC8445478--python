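{
  "version": 1,
  "description": "Packaged default parameters for the 15-unit, three-chain phi ('ghost percept') circuit. Chain-unit taus ascend from relay to output; primer units have fast drive and slow decay via sub-unity self-feedback with no negative bias; primer-to-adjacent-output couplings are weak enough that a single saturated primer cannot push an undriven output above threshold. These defaults satisfy the circuit's qualitative behavioral contracts and are a package choice, not a published parameterization.",
  "chain_tau": [1.0, 2.0, 3.0, 4.0],
  "chain_weight": 2.0,
  "chain_bias": -0.5,
  "input_weight": 2.0,
  "primer_tau": 2.0,
  "primer_self_weight": 0.9,
  "primer_drive_weight": 2.0,
  "primer_coupling": 0.8,
  "threshold": 0.5
}
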