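person_id,system,code,dose_value,dose_unit,administered_at
P1,ATC,H02AB02,1.0,mg,2020-03-01T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-02T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-03T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-04T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-05T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-06T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-07T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-08T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-09T10:00:00
P1,ATC,H02AB02,1.0,mg,2020-03-10T10:00:00
P4,ATC,H02AB02,1.0,mg,2020-03-03T10:00:00
P4,ATC,H02AB02,1.0,mg,2020-03-04T10:00:00
P4,ATC,H02AB02,1.0,mg,2020-03-06T10:00:00
P4,ATC,H02AB02,1.0,mg,2020-03-07T10:00:00
P4,ATC,H02AB02,1.0,mg,2020-03-08T10:00:00
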