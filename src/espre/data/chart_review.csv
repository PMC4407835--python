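nct_id,n_enrolled,n_output,n_hits,n_additional
NCT00072384,1,2,1,0
NCT00134030,9,18,9,2
NCT00274937,1,2,1,0
NCT00335556,2,4,0,0
NCT00343694,3,6,1,1
NCT00379340,1,2,0,0
NCT00382109,2,4,0,0
NCT00553202,6,12,4,1
NCT00557193,1,2,1,0
NCT01190930,12,24,12,1
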