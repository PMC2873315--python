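# Two rival first-order models of the same observed quantity.
#
# Both share the steady state x* = 0 at zero basal input, so they are
# indistinguishable at rest; they differ only in the relaxation rate.
# Try:
#   discrim ic        --config examples/first_order_pair.yaml
#   discrim input     --config examples/first_order_pair.yaml
#   discrim simulate  --config examples/first_order_pair.yaml --ic 1
model1:
  states: [x]
  params: {k: 1.0}
  drift: ["-k*x"]
  input_map: [["1"]]
  output_map: [x]
  basal_input: [0.0]
model2:
  states: [x]
  params: {k: 2.0}
  drift: ["-k*x"]
  input_map: [["1"]]
  output_map: [x]
  basal_input: [0.0]
steady_state_guess: [0.0]
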