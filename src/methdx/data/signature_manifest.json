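{
 "hypo_up_signature.tsv": "5296ea942c737fad9a47d54e5d0304622da9c9698b7d18ed3019a0bfc52d93be",
 "hyper_down_signature.tsv": "c256025359a950adcce18e7ca15ad4ff45902e147df7c6354dcc5d9c0e198b09"
}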