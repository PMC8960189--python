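Place the public NCBI RefSeq FASTA for NP_002007.1 (human profilaggrin)
here as NP_002007.1.fasta to enable the profilaggrin reference checks.
It is not redistributed with the package.
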