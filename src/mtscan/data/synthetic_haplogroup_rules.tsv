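variant	carrier_haplogroups	back_mutated_haplogroups
m.10550A>G	K;K1;K1A1B;K1A1B2A1
m.1189T>C	K1;K1A1B;K1A1B2A1
m.15924A>G	K1A1B;K1A1B2A1;T2B;H5A
m.15758A>G	K1A1B2A1
m.3197T>C	U5;U5B;U5B1;U5B1B2
m.5656A>G	U5B;U5B1;U5B1B2
m.217T>C	U5B1B2;T2
m.73A>G	K;K1;K1A1B;K1A1B2A1;U5;U5B;U5B1;U5B1B2;T2;T2B;H5A	H2A2
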