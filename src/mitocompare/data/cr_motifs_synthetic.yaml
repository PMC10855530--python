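# Synthetic teleost-style control-region motif library, version 1.
#
# Consensus strings for the central conserved domains (CSB-F/E/D/C/B/A) and
# conserved sequence blocks (CSB-1/2/3) of the fish mitochondrial control
# region.  Block lengths follow the values reported for grouper CRs
# (CSB-D the longest CCD at 33 bp; CSB-A/B/C/E/F at 18/18/28/19/20 bp;
# CSB-1/2/3 at 23/18/20 bp).  The strings themselves are CONSTRUCTED
# stand-ins in teleost CR style (AT-rich, pyrimidine-tract CSB-2 etc.),
# not transcriptions of any published figure; they anchor synthetic-data
# tests and may be replaced by a user-curated library.
version: 1
order: [CSB-F, CSB-E, CSB-D, CSB-C, CSB-B, CSB-A, CSB-1, CSB-2, CSB-3]
blocks:
  CSB-F: ATGTAGTAAGAGCCTACCAT          # 20 bp
  CSB-E: AGGGACAATTATTGTGGGG           # 19 bp
  CSB-D: TATTATTCCTGGCATCTGGTTCCTATTTCAGGG  # 33 bp
  CSB-C: TAAACCCCCCTACCCCCCTAAACTCCTG  # 28 bp
  CSB-B: CAAACCCCGAAACCAGGA            # 18 bp
  CSB-A: ACATAACTGATATCAAGG            # 18 bp
  CSB-1: TTAATGCTTGTTAGACATAATAT       # 23 bp
  CSB-2: CCCCCTTTTTCCCCCCTT            # 18 bp
  CSB-3: TGTCAAACCCCCCTACCCCC          # 20 bp
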