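patient,surrogate,amp_mean,amp_sd,cv_percent,bpm,pearson_r,volume_change_pct,oi,dsc
1,bellows,0.245,0.210,85.6,9.6,0.934,-0.17,0.997,0.996
1,rpm,0.233,0.180,77.1,9.6,0.934,-0.17,0.997,0.996
2,bellows,0.280,0.176,62.8,16.9,0.974,0.00,0.996,0.996
2,rpm,0.239,0.152,63.8,16.9,0.974,0.00,0.996,0.996
3,bellows,0.425,0.269,63.3,22.3,0.881,0.10,0.992,0.993
3,rpm,0.368,0.258,70.1,22.3,0.881,0.10,0.992,0.993
4,bellows,0.310,0.210,67.9,23.2,0.908,0.08,0.991,0.992
4,rpm,0.244,0.168,69.0,23.2,0.908,0.08,0.991,0.992
5,bellows,0.232,0.214,92.1,12.6,0.969,0.06,0.997,0.997
5,rpm,0.276,0.209,75.8,12.6,0.969,0.06,0.997,0.997
6,bellows,0.296,0.246,83.2,13.6,0.968,-0.17,0.993,0.992
6,rpm,0.326,0.251,77.0,13.6,0.968,-0.17,0.993,0.992
7,bellows,0.340,0.254,74.7,18.6,0.985,-1.23,0.995,0.989
7,rpm,0.350,0.241,69.0,18.6,0.985,-1.23,0.995,0.989
8,bellows,0.402,0.265,65.9,14.2,0.977,0.07,0.993,0.993
8,rpm,0.386,0.273,70.7,14.2,0.977,0.07,0.993,0.993
9,bellows,0.186,0.216,115.7,7.0,0.967,-0.50,0.990,0.988
9,rpm,0.236,0.226,95.6,7.0,0.967,-0.50,0.990,0.988
10,bellows,0.324,0.253,78.2,21.8,0.911,-1.17,0.992,0.986
10,rpm,0.334,0.224,67.3,21.8,0.911,-1.17,0.992,0.986
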