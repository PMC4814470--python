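Optional external records for the two accession-based acceptance checks.
They require network access and are not bundled. To enable the checks, fetch:

  CP003222.2.fasta  Flavobacterium columnare ATCC 49512 chromosome
  FCL-2.fasta       Flavobacterium phage FCL-2 (accession KP054477)

e.g. via NCBI efetch:
  efetch -db nuccore -id CP003222.2 -format fasta > CP003222.2.fasta
  efetch -db nuccore -id KP054477 -format fasta > FCL-2.fasta
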