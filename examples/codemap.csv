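guideline_system,guideline_code,local_system,local_code
ICD10,U07.1,ICD10,U07.1
SNOMED,57485005,SNOMED,57485005
ATC,H02AB02,ATC,H02AB02
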