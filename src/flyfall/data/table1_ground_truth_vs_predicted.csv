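hour,predicted,ground_truth,potential_fp,actual_fp,fn
13,12,10,2,1,0
14,13,12,1,0,0
15,17,15,2,0,0
16,30,29,2,0,1
18,66,62,4,0,0
19,109,97,13,2,1
21,6,6,0,0,0
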