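subject_id,joint,side,rom,max_moment,cumulative_moment,n_trials
S001,elbow,left,69.0667,18.6742,18.6742,3
S001,elbow,right,72.8057,18.8817,18.8817,3
S001,neck,midline,46.6201,9.57676,9.57677,3
S001,shoulder,left,89.6912,41.434,41.434,3
S001,shoulder,right,95.3204,46.6942,46.6942,3
S002,elbow,left,68.8644,19.3263,19.3263,3
S002,elbow,right,69.0329,20.2987,20.2987,3
S002,neck,midline,44.3111,9.05992,9.05992,3
S002,shoulder,left,95.9491,44.0315,44.0315,3
S002,shoulder,right,92.3069,46.2932,46.2932,3
S003,elbow,left,73.7482,14.2382,14.2382,3
S003,elbow,right,73.2322,15.517,15.5169,3
S003,neck,midline,43.2946,7.54239,7.54239,3
S003,shoulder,left,93.5514,32.1202,32.1201,3
S003,shoulder,right,91.0768,34.4471,34.4471,3
S004,elbow,left,63.323,16.2273,16.2273,3
S004,elbow,right,67.8382,17.5648,17.5648,3
S004,neck,midline,41.4064,7.77282,7.77282,3
S004,shoulder,left,85.1143,36.1257,36.1257,3
S004,shoulder,right,87.9189,37.7189,37.7189,3
S005,elbow,left,65.5391,14.6911,14.6911,3
S005,elbow,right,62.3792,17.5208,17.5209,3
S005,neck,midline,37.7978,7.71444,7.71444,3
S005,shoulder,left,86.909,35.9696,35.9696,3
S005,shoulder,right,83.052,38.904,38.904,3
S006,elbow,left,64.4136,20.2409,20.2409,3
S006,elbow,right,69.726,21.8264,21.8264,3
S006,neck,midline,40.4258,10.0846,10.0846,3
S006,shoulder,left,83.4072,44.7434,44.7434,3
S006,shoulder,right,84.964,48.3194,48.3195,3
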