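{
 "clustering_chosen_k": 8,
 "clustering_criterion_k4": 0.23314262456437146,
 "fc_g1_planted_axis_abs_rho": 0.9981688918858792,
 "fc_variance_explained_first_k": 0.6278639642175475,
 "mean_cross_task_diversity": 0.15300852587371921,
 "mean_inter_areal_dissimilarity": 1.0207502413787508,
 "mean_intra_areal_dissimilarity": 0.45915329153531453,
 "mpc_g1_planted_axis_abs_rho": 0.92861319417207,
 "mpc_variance_explained_first_k": 0.7913081392931838,
 "n_flag_high_dissimilarity": 0,
 "n_flag_low_dissimilarity": 0,
 "p_spin_diversity_vs_inter": 0.4079601990049751,
 "p_spin_inter_vs_histological": 0.2935323383084577,
 "p_spin_intra_task_sd_vs_diversity_partial_tsnr": 0.009950248756218905,
 "pca_pc1_variance_explained": 0.27543641068721747,
 "rho_diversity_vs_inter": 0.1801125703564728,
 "rho_inter_vs_global_strength": 0.44953095684802996,
 "rho_inter_vs_histological": -0.26210131332082554,
 "rho_inter_vs_participation": -0.12645403377110692,
 "rho_intra_task_sd_vs_diversity_partial_tsnr": 0.5138762799410694,
 "rho_intra_vs_inter": -0.38742964352720444,
 "sc_g1_planted_axis_abs_rho": 0.5072103236568575,
 "sc_variance_explained_first_k": 0.5807506735919059
}
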