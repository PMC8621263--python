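{
 "alexnet3d": 129354,
 "vgg3d": 694506,
 "resnet3d": 521706
}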