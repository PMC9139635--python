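# Desk-scale configuration: tiny ConvNeXt preset on 64x64 frames.
model:
  stage_widths: [16, 32, 64, 128]
  input_size: 64
train:
  epochs: 10
  input_size: 64
  seed: 1
phantom:
  frame_size: 64
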