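# factor: 0.8
# channel: ka
# bin_width: 1.0
# duration: 10.0
0.5,2.5,7.1
3.9

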