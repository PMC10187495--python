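date,count
2020-02-13,0
2020-03-05,100
2020-03-19,1500
2020-03-26,5000
2020-06-11,350
2020-10-29,16000
2021-01-07,25000
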