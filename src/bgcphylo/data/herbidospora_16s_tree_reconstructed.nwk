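(Acrocarpospora_corrugata:0.020,(H_mongoliensis:0.010,(H_cretacea:0.008,(H_yilanensis:0.006,(H_daliensis:0.004,H_sakaeratensis:0.004):0.003):0.003):0.004):0.012);
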