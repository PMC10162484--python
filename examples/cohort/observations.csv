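person_id,system,code,value_num,value_unit,value_code,observed_at
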