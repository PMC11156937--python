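fog_class,split,n_events,duration_min
start_hesitation,train,107,39.8
start_hesitation,public_test,53,3.7
start_hesitation,private_test,16,0.4
turn,train,1948,316.4
turn,public_test,630,113.2
turn,private_test,309,39.5
walking,train,395,43.5
walking,public_test,262,22.5
walking,private_test,66,3.1
notype,train,1032,83.2
notype,public_test,0,0.0
notype,private_test,0,0.0
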