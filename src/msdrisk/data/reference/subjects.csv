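subject_id,sex,age,height_cm,weight_kg,readiness_score
S001,male,28.0148,178.569,71.8513,4
S002,male,32.1683,148.038,71.0372,4
S003,male,30.1014,169.196,59.8658,8
S004,female,28.7665,192.418,61.1048,6
S005,female,42.3909,178.595,64.8283,7
S006,female,30.6779,177.225,77.5178,6
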