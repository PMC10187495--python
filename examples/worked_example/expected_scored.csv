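id,group,phase,score,sign_class,n_tokens,n_matches
t01,authority,1,-0.8732,negative,7,2
t02,expert,1,-1.9672,negative,9,3
t03,authority,1,1.0452,positive,7,3
t04,authority,2,0.0040,positive,5,1
t05,expert,2,-0.8408,negative,7,2
t09,authority,2,0.4877,positive,4,1
t10,expert,3,-1.3715,negative,8,2
t11,expert,3,1.1536,positive,6,2
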