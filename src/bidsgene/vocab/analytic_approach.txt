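snp genotyping array
whole genome sequencing
whole exome sequencing
rna sequencing
targeted genome sequencing
methylation array
gene expression array
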