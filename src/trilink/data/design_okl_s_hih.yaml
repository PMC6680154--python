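# Three-point cross design: Oakleaf - S locus - Hose in Hose.
# Informative thrum parents carry HIH in coupling and OKL in repulsion to S;
# testers are wild-type pins (okl,s,hih homozygotes).
name: okl_s_hih
loci:
  - name: OKL
    dominance: mutant_dominant
    symbols: [OKL, okl]
  - name: S
    dominance: composite_S
  - name: HIH
    dominance: mutant_dominant
    symbols: [HIH, hih]
parents:
  - id: thrum-1
    role: informative
    haplotypes: ["okl,S,HIH", "OKL,s,hih"]
  - id: thrum-2
    role: informative
    haplotypes: ["okl,S,HIH", "OKL,s,hih"]
  - id: pin-1
    role: tester
    haplotypes: ["okl,s,hih", "okl,s,hih"]
  - id: pin-2
    role: tester
    haplotypes: ["okl,s,hih", "okl,s,hih"]
  - id: pin-3
    role: tester
    haplotypes: ["okl,s,hih", "okl,s,hih"]
  - id: pin-4
    role: tester
    haplotypes: ["okl,s,hih", "okl,s,hih"]
  - id: pin-5
    role: tester
    haplotypes: ["okl,s,hih", "okl,s,hih"]
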