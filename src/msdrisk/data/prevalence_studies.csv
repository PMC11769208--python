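label,country,sample_size,mean_age,age_sd,neck,shoulder,elbow
Ribeiro2016,Portugal,409,40,9,0.501,0.378,0.072
Adap2017,India,212,31,6,0.331,0.346,0.019
Ryu2014,USA,531,30,7,0.333,0.448,0.055
Chung2013,Taiwan,1914,34,8,0.434,0.440,0.245
Arvidsson2016,Sweden,925,47,10,0.390,0.453,0.273
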