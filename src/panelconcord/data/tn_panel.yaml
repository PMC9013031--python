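# Matched tumor-normal panel fixture. The mean-read-depth requirement is
# tiered on tumor cellularity; the cap is unlimited.
name: TN
matched_normal: true
genes_file: tn_genes.txt
af_floor: 0.05
min_alt_reads: 4
mean_depth: 600
depth_rule:
  tiered:
    high_cellularity: 200
    mid_cellularity: 250
    low_cellularity: 500
reporting_cap: unlimited
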