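# Tumor-only panel fixture. Analytical parameters (AF floor, supporting-read
# minimum) are package defaults, not vendor-disclosed values.
name: TO
matched_normal: false
genes_file: to_genes.txt
af_floor: 0.02
min_alt_reads: 4
mean_depth: 3000
depth_rule:
  fixed: 0
reporting_cap: 14
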