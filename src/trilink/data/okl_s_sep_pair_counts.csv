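cross_id,informative_parent,class_a,class_b,count
pooled,thrum-1,OKL=mutant;S=thrum;SEP=wild_type,OKL=wild_type;S=pin;SEP=mutant,592
pooled,thrum-1,OKL=mutant;S=pin;SEP=mutant,OKL=wild_type;S=thrum;SEP=wild_type,6
pooled,thrum-1,OKL=wild_type;S=pin;SEP=wild_type,OKL=mutant;S=thrum;SEP=mutant,2
pooled,thrum-1,OKL=mutant;S=pin;SEP=wild_type,OKL=wild_type;S=thrum;SEP=mutant,1
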