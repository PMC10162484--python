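person_id,ward_type,start,end
P1,ICU,2020-03-01T00:00:00,2020-03-11T00:00:00
P2,ICU,2020-03-01T00:00:00,2020-03-11T00:00:00
P3,ICU,2020-03-01T00:00:00,2020-03-11T00:00:00
P4,ICU,2020-03-03T00:00:00,2020-03-09T00:00:00
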