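>GATA3 GATA3
A [ 0.9100 0.0300 0.9100 0.0300 0.9100 0.9100 ]
C [ 0.0300 0.0300 0.0300 0.0300 0.0300 0.0300 ]
G [ 0.0300 0.9100 0.0300 0.0300 0.0300 0.0300 ]
T [ 0.0300 0.0300 0.0300 0.9100 0.0300 0.0300 ]
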