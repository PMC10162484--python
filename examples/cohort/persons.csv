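person_id,birth_year,sex
P1,1958,F
P2,1973,M
P3,1964,F
P4,1951,M
P5,1980,F
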