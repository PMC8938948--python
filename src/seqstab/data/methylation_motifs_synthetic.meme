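MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF syn_meth_01
letter-probability matrix: alength= 4 w= 8 nsites= 24 E= 1.2e-8
 0.850000 0.050000 0.050000 0.050000
 0.020000 0.900000 0.050000 0.030000
 0.000000 0.000000 1.000000 0.000000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.000000 1.000000 0.000000 0.000000
 0.050000 0.050000 0.850000 0.050000
 0.900000 0.040000 0.030000 0.030000

MOTIF syn_meth_02
letter-probability matrix: alength= 4 w= 6 nsites= 31 E= 3.4e-6
 0.050000 0.050000 0.050000 0.850000
 0.000000 0.000000 1.000000 0.000000
 0.100000 0.700000 0.100000 0.100000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.000000 1.000000 0.000000 0.000000

MOTIF syn_meth_03
letter-probability matrix: alength= 4 w= 10 nsites= 18 E= 7.7e-5
 0.050000 0.800000 0.100000 0.050000
 0.000000 1.000000 0.000000 0.000000
 0.050000 0.050000 0.850000 0.050000
 0.900000 0.030000 0.040000 0.030000
 0.050000 0.050000 0.050000 0.850000
 0.000000 0.000000 1.000000 0.000000
 0.100000 0.100000 0.700000 0.100000
 0.050000 0.050000 0.050000 0.850000
 0.850000 0.050000 0.050000 0.050000
 0.100000 0.700000 0.100000 0.100000

MOTIF syn_meth_04
letter-probability matrix: alength= 4 w= 7 nsites= 27 E= 9.1e-7
 0.050000 0.050000 0.850000 0.050000
 0.900000 0.040000 0.030000 0.030000
 0.000000 1.000000 0.000000 0.000000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.100000 0.100000 0.100000 0.700000
 0.100000 0.700000 0.100000 0.100000
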