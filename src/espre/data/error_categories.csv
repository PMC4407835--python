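category,description,n_errors
1,previously enrolled in the trial or therapy at a different institution,3
2,new diagnosis treated with standard-of-care therapy,4
3,correct diagnosis but different disease stage,5
4,correct diagnosis but incorrect relapse status,5
5,wrong diagnosis due to confusion between disease sub-categories,13
6,wrong diagnosis for other reasons,12
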