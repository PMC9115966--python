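# Example full-pipeline configuration (see petflux.pipeline.RunConfig
# for every key and its default).
seed: 7
n_patients: 15
models: [patlak, 2C3K, spline]
t_star: 10.0
gsea_methods: [pearson]
n_perm: 2000
alpha_numerator: 0.035
n_genes: 2000
planted:
  - [PW_PLANTED, 50, 0.8, kflux_2C3K]
n_null_sets: 99
null_set_size: 50
noise_scale: 1.0
micro_parameter_gsea: true
fp_study_datasets: 0
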