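# Versioned discriminator architecture table.
#
# Six canonical image-classification DCNNs translated to 1-D fingerprint
# input: the bit vector passes through a dense input projection, is reshaped
# to a single-channel 1-D signal, and then flows through the listed layers.
# 2-D kernels of the canonical architectures become 1-D kernels of the same
# extent; channel widths are scaled down to suit a length-168 signal.  A
# final 2-unit dense output layer (softmax in the loss) is appended
# automatically by the builder.
#
# VGGNet11 and VGGNet13 are derived from VGGNet16 by dropping the layer
# groups tagged "pound" and "asterisk" respectively.
version: 1
input_projection:
  activation: relu
architectures:
  LeNet5:
    - {kind: conv, filters: 6, kernel: 5, activation: tanh}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 16, kernel: 5, activation: tanh}
    - {kind: pool, size: 2}
    - {kind: flatten}
    - {kind: dense, units: 120, activation: tanh}
    - {kind: dense, units: 84, activation: tanh}
  AlexNet:
    - {kind: conv, filters: 8, kernel: 11, activation: relu}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 16, kernel: 5, activation: relu}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 24, kernel: 3, activation: relu}
    - {kind: conv, filters: 24, kernel: 3, activation: relu}
    - {kind: conv, filters: 16, kernel: 3, activation: relu}
    - {kind: pool, size: 2}
    - {kind: flatten}
    - {kind: dense, units: 64, activation: relu}
    - {kind: dense, units: 32, activation: relu}
  ZFNet:
    - {kind: conv, filters: 8, kernel: 7, activation: relu}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 16, kernel: 5, activation: relu}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 24, kernel: 3, activation: relu}
    - {kind: conv, filters: 24, kernel: 3, activation: relu}
    - {kind: conv, filters: 16, kernel: 3, activation: relu}
    - {kind: pool, size: 2}
    - {kind: flatten}
    - {kind: dense, units: 64, activation: relu}
    - {kind: dense, units: 32, activation: relu}
  VGGNet16:
    - {kind: conv, filters: 4, kernel: 3, activation: relu}
    - {kind: conv, filters: 4, kernel: 3, activation: relu, group: pound}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 8, kernel: 3, activation: relu}
    - {kind: conv, filters: 8, kernel: 3, activation: relu, group: pound}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 16, kernel: 3, activation: relu}
    - {kind: conv, filters: 16, kernel: 3, activation: relu}
    - {kind: conv, filters: 16, kernel: 3, activation: relu, group: pound_asterisk}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 32, kernel: 3, activation: relu}
    - {kind: conv, filters: 32, kernel: 3, activation: relu}
    - {kind: conv, filters: 32, kernel: 3, activation: relu, group: pound_asterisk}
    - {kind: pool, size: 2}
    - {kind: conv, filters: 32, kernel: 3, activation: relu}
    - {kind: conv, filters: 32, kernel: 3, activation: relu}
    - {kind: conv, filters: 32, kernel: 3, activation: relu, group: pound_asterisk}
    - {kind: pool, size: 2}
    - {kind: flatten}
    - {kind: dense, units: 64, activation: relu}
    - {kind: dense, units: 32, activation: relu}
  VGGNet13:
    base: VGGNet16
    drop_groups: [asterisk]
  VGGNet11:
    base: VGGNet16
    drop_groups: [pound, asterisk]
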