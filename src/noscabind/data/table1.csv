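compound_id,glide_xp_score,u_vdw,u_elec,u_cav,predicted_dg,kd_mean,kd_sd,experimental_dg
1,-5.505,-55.418,30.32,0.846,-4.946,152,1.0,-5.246
2a,-5.563,-57.935,83.89,1.064,-5.603,81,8.0,-5.587
2b,-6.337,-54.219,87.74,1.649,-5.911,40,8.0,-6.006
2c,-5.684,-46.846,119.9,1.442,-5.344,54,9.1,-5.827
2d,-5.868,-57.614,129.3,1.857,-6.560,22,4.0,-6.360
2e,-5.790,-59.016,63.66,1.335,-5.837,86,6.0,-5.551
2f,-6.412,-58.032,68.17,2.032,-6.452,14,1.0,-6.628
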