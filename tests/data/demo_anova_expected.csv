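region,measure,effect,SS,df,MS,F,p
hippocampus,MK,group,0.2456717952454359,1,0.2456717952454359,26.41532752003618,0.0004380258713325
hippocampus,MK,subject(group),0.0930035014932495,10,0.0093003501493249,,
hippocampus,MK,time,0.2105012197442839,3,0.0701670732480946,47.26933036546323,1.7517173209808173e-11
hippocampus,MK,group:time,0.2305820352418852,3,0.0768606784139617,51.77859973177437,5.659871206621363e-12
hippocampus,MK,residual,0.0445323041635648,30,0.0014844101387854,,
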