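compound_id,glide_xp_score,u_vdw,u_elec,u_cav,predicted_dg,kd_mean,kd_sd,experimental_dg
5a,-5.639,-53.39,87.69,0.835,-5.164,68,0.7,-5.691
6a,-5.997,-62.81,67.52,0.820,-5.707,,,
6b,-6.918,-60.25,57.27,0.988,-5.622,,,
6c,-6.087,-63.68,41.56,0.846,-5.639,91,8.0,-5.518
6d,-6.882,-64.85,35.95,0.865,-5.708,,,
6e,-6.907,-61.85,79.091,0.972,-5.852,,,
6f,-7.252,-62.62,76.07,1.287,-6.189,38,4.0,-6.036
6g,-5.767,-61.34,64.56,0.445,-5.227,,,
6h,-7.196,-65.08,55.79,1.033,-6.003,,,
6i,-5.712,-62.12,41.14,0.723,-5.407,79,8.0,-5.602
6j,-5.402,-57.50,7.551,0.776,-4.923,228,10.0,-4.973
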