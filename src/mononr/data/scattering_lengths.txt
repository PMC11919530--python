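# Bound coherent neutron scattering lengths, fm.
# D denotes the deuteron (2H). Override by editing or loading another table.
H -3.739
D 6.671
C 6.646
N 9.36
O 5.803
P 5.13
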