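phantom,volume_change_pct,oi,dsc,centroid_dx_mm,centroid_dy_mm,centroid_dz_mm,itv_true_diff_bellows_pct,itv_true_diff_rpm_pct
1,-1.77,0.974,0.965,0.1,0.1,-0.1,16.67,15.19
2,-1.25,0.971,0.965,0.0,0.0,-0.2,25.12,24.18
3,0.46,0.964,0.966,0.1,0.0,-0.1,2.08,2.53
4,0.61,0.959,0.962,0.0,0.0,-0.2,12.10,12.64
5,-1.21,0.967,0.961,0.0,0.0,-0.3,15.98,14.97
6,-0.70,0.968,0.964,0.0,0.0,-0.2,9.73,9.09
7,0.40,0.957,0.959,0.0,0.0,-0.3,6.90,7.27
8,1.15,0.957,0.963,0.0,0.0,-0.9,12.21,13.22
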