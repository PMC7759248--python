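participant_id,wave,q3,fair_clr
617,2,4,-1.49
419,1,5,-1.54
419,2,5,-1.48
643,2,6,-1.24
793,3,6,1.05
170,3,6,1.49
569,1,7,2.10
133,2,7,1.73
569,2,7,2.09
133,3,7,1.69
569,3,7,1.88
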