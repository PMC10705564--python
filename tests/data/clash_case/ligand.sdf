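
     RDKit          3D

  6  5  0  0  0  0  0  0  0  0999 V2000
   -1.2840    1.2100    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7700   -0.2420    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7700   -0.2420    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2840    1.2100    0.0000 S   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2840   -0.9680    1.2570 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.2840   -0.9680   -1.2570 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  2  5  1  0
  3  6  1  0
M  END
$$$$
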