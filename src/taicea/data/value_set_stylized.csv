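dimension,level,decrement
mobility,1,0.000
mobility,2,0.045
mobility,3,0.100
mobility,4,0.190
mobility,5,0.270
self_care,1,0.000
self_care,2,0.045
self_care,3,0.095
self_care,4,0.175
self_care,5,0.240
usual_activities,1,0.000
usual_activities,2,0.040
usual_activities,3,0.085
usual_activities,4,0.160
usual_activities,5,0.220
pain_discomfort,1,0.000
pain_discomfort,2,0.050
pain_discomfort,3,0.110
pain_discomfort,4,0.200
pain_discomfort,5,0.270
anxiety_depression,1,0.000
anxiety_depression,2,0.045
anxiety_depression,3,0.095
anxiety_depression,4,0.175
anxiety_depression,5,0.240
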