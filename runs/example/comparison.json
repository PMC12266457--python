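{
 "n": 10,
 "mean_auc_a": 0.9955771053841851,
 "mean_auc_b": 0.9956354471942215,
 "t_statistic": 0.2112145677510392,
 "t_pvalue": 0.8374249524660299,
 "wilcoxon_W": 21.0,
 "wilcoxon_pvalue": 0.556640625,
 "median_d": 0.0004107980814833656,
 "q1_d": -0.0003670459172102625,
 "q3_d": 0.0005638948605197203,
 "n_outliers": 1
}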