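phantom,surrogate,amp_mean,amp_sd,cv_percent,bpm,pearson_r
1,bellows,0.146,0.141,96.2,13.9,0.996
1,rpm,0.147,0.143,97.3,13.9,0.996
2,bellows,0.095,0.143,150.2,11.9,0.999
2,rpm,0.094,0.146,155.1,11.9,0.999
3,bellows,0.307,0.254,83.0,16.9,0.993
3,rpm,0.305,0.259,84.8,16.9,0.993
4,bellows,0.171,0.166,97.2,14.9,0.987
4,rpm,0.174,0.168,96.5,14.9,0.987
5,bellows,0.206,0.177,85.9,7.2,0.990
5,rpm,0.180,0.193,107.4,7.2,0.990
6,bellows,0.271,0.187,69.1,22.0,0.996
6,rpm,0.281,0.195,69.3,22.0,0.996
7,bellows,0.218,0.210,96.5,19.9,0.994
7,rpm,0.255,0.198,77.8,19.9,0.994
8,bellows,0.110,0.150,136.9,13.0,0.998
8,rpm,0.103,0.155,151.1,13.0,0.998
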