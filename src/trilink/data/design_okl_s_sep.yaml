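# Three-point cross design: Oakleaf - S locus - sepaloid.
# Informative Oakleaf thrums carry OKL in coupling to S and the recessive
# sep allele in repulsion to S; the tester is a sepaloid pin.
name: okl_s_sep
loci:
  - name: OKL
    dominance: mutant_dominant
    symbols: [OKL, okl]
  - name: S
    dominance: composite_S
  - name: SEP
    dominance: mutant_recessive
    symbols: [SEP, sep]
parents:
  - id: thrum-1
    role: informative
    haplotypes: ["OKL,S,SEP", "okl,s,sep"]
  - id: thrum-2
    role: informative
    haplotypes: ["OKL,S,SEP", "okl,s,sep"]
  - id: thrum-3
    role: informative
    haplotypes: ["OKL,S,SEP", "okl,s,sep"]
  - id: thrum-4
    role: informative
    haplotypes: ["OKL,S,SEP", "okl,s,sep"]
  - id: pin-1
    role: tester
    haplotypes: ["okl,s,sep", "okl,s,sep"]
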