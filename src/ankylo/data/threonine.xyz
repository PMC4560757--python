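17
synthetic threonine-like conformer (RDKit ETKDG + MMFF, seed 7); 4 C, 1 N, 3 O, 9 H
C -2.483178 -0.805415 -0.241732
C -0.977034 -0.743634 -0.476017
O -0.753952 0.030074 -1.664748
C -0.237346 -0.096907 0.713067
N -0.321434 1.395780 0.653203
C 1.217997 -0.576532 0.725792
O 1.595079 -1.729595 0.863621
O 2.122797 0.418451 0.578040
H -2.984937 -1.241510 -1.112437
H -2.722555 -1.411544 0.637200
H -2.907968 0.195032 -0.105218
H -0.604597 -1.754468 -0.674111
H -1.027674 0.938673 -1.427696
H -0.672981 -0.423352 1.664748
H 0.394035 1.688301 -0.024054
H 0.051827 1.754468 1.535282
H 2.984937 -0.049562 0.578138
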