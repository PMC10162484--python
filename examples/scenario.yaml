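n_patients: 400
start_date: 2020-03-01
end_date: 2021-05-31
p_population: 0.5
adherence_before: 0.1
adherence_after: 0.75
switch_date: 2020-06-16
mean_stay_days: 10
seed: 42
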