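# demo pipeline configuration: small, fast, deterministic
seed = 11
alignment.n_contigs = 200
alignment.snp_rate_per_kb = 0.81
alignment.base_error_rate = 0.0
alignment.homopolymer_decoy_rate = 0.2
alignment.indel_decoy_rate = 0.2
alignment.triallelic_decoy_rate = 0.2
alignment.low_minor_decoy_rate = 0.1
alignment.edge_decoy_rate = 0.2
alignment.lowqual_flank_decoy_rate = 0.2
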