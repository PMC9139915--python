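feature_name,icc
morph_volume,0.679
morph_surface_area,0.967
morph_surface_to_volume_ratio,0.793
morph_sphericity,0.782
morph_compactness1,0.654
morph_compactness2,0.67
morph_spherical_disproportion,0.984
morph_asphericity,0.324
morph_max_diameter_3d,0.755
morph_major_axis_length,0.909
morph_minor_axis_length,0.725
morph_least_axis_length,0.769
morph_elongation,0.806
morph_flatness,0.896
morph_volume_density_aabb,0.717
morph_area_density_aabb,0.761
morph_volume_density_aee,0.837
morph_area_density_aee,0.761
intensity_peak_local,0.876
intensity_peak_global,0.863
tlg,0.729
stat_mean,0.849
stat_variance,0.875
stat_skewness,0.855
stat_kurtosis,0.429
stat_median,0.785
stat_min,0.872
stat_p5,0.727
stat_p10,0.667
stat_p25,0.916
stat_p75,0.964
stat_p90,0.875
stat_p95,0.811
stat_max,0.712
stat_iqr,0.947
stat_range,0.717
stat_mad,0.712
stat_rmad,0.854
stat_medad,0.972
stat_cov,0.7
stat_qcod,0.868
stat_energy,0.846
stat_rms,0.806
ih_mean,0.722
ih_variance,0.783
ih_skewness,0.687
ih_kurtosis,0.88
ih_median,0.685
ih_min,0.668
ih_p10,0.711
ih_p25,0.758
ih_p75,0.868
ih_p90,0.913
ih_max,0.959
ih_mode,0.959
ih_iqr,0.751
ih_range,0.964
ih_mad,0.953
ih_rmad,0.881
ih_medad,0.677
ih_cov,0.663
ih_qcod,0.922
ih_entropy,0.752
ih_uniformity,0.811
ih_max_gradient,0.339
ih_max_gradient_level,0.518
ih_min_gradient,0.488
ih_min_gradient_level,0.456
ivh_v10,0.672
ivh_v25,0.847
ivh_v75,0.795
ivh_v90,0.882
ivh_i10,0.842
ivh_i25,0.801
ivh_i75,0.825
ivh_i90,0.959
ivh_v10_minus_v90,0.485
ivh_v25_minus_v75,0.3
ivh_i10_minus_i90,0.722
ivh_i25_minus_i75,0.868
glcm_joint_max,0.843
glcm_joint_average,0.978
glcm_joint_variance,0.674
glcm_joint_entropy,0.802
glcm_diff_average,0.72
glcm_diff_variance,0.732
glcm_diff_entropy,0.968
glcm_sum_average,0.82
glcm_sum_variance,0.895
glcm_sum_entropy,0.747
glcm_asm,0.735
glcm_contrast,0.914
glcm_dissimilarity,0.979
glcm_inverse_difference,0.734
glcm_inverse_difference_norm,0.959
glcm_inverse_difference_moment,0.923
glcm_inverse_difference_moment_norm,0.697
glcm_inverse_variance,0.94
glcm_correlation,0.856
glcm_autocorrelation,0.833
glcm_cluster_tendency,0.881
glcm_cluster_shade,0.535
glcm_cluster_prominence,0.37
glcm_info_corr1,0.501
glcm_info_corr2,0.653
glcm_mcc,0.41
glrlm_short_run_emphasis,0.946
glrlm_long_run_emphasis,0.692
glrlm_low_gl_emphasis,0.669
glrlm_high_gl_emphasis,0.903
glrlm_short_run_low_gl_emphasis,0.907
glrlm_short_run_high_gl_emphasis,0.723
glrlm_long_run_low_gl_emphasis,0.269
glrlm_long_run_high_gl_emphasis,0.32
glrlm_gl_nonuniformity,0.836
glrlm_gl_nonuniformity_norm,0.671
glrlm_run_nonuniformity,0.712
glrlm_run_nonuniformity_norm,0.974
glrlm_run_percentage,0.877
glrlm_gl_variance,0.828
glrlm_run_variance,0.372
glrlm_run_entropy,0.908
glszm_short_zone_emphasis,0.976
glszm_long_zone_emphasis,0.428
glszm_low_gl_emphasis,0.882
glszm_high_gl_emphasis,0.829
glszm_short_zone_low_gl_emphasis,0.753
glszm_short_zone_high_gl_emphasis,0.658
glszm_long_zone_low_gl_emphasis,0.371
glszm_long_zone_high_gl_emphasis,0.325
glszm_gl_nonuniformity,0.743
glszm_gl_nonuniformity_norm,0.824
glszm_zone_nonuniformity,0.846
glszm_zone_nonuniformity_norm,0.793
glszm_zone_percentage,0.66
glszm_gl_variance,0.866
glszm_zone_variance,0.321
glszm_zone_entropy,0.731
ngtdm_coarseness,0.765
ngtdm_contrast,0.671
ngtdm_busyness,0.459
ngtdm_complexity,0.38
ngtdm_strength,0.331
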