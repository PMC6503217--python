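# Full-pipeline configuration: simulate a 6-genome collection and run all
# seven analysis stages. Thresholds shown are the defaults made explicit.

[simulate]
n_genomes = 6
seed = 7
subs_rate = 0.02
n_core_genes = 30
n_ribosomal = 10
n_accessory_pool = 30
gain_rate = 0.1
loss_rate = 0.3
psym_transfer_rate = 0.3
chromosome_len = 30000
mean_gene_len = 150

[[simulate.plasmid_plan]]
kind = "plasmid"
n_genes = 6
length = 12000

[[simulate.plasmid_plan]]
kind = "psym"
n_genes = 12
length = 20000

[filter]
min_draft_length = 6000000

[markers]
role_tag = "ribosomal"
model = "poisson"
max_rf_quantile = 0.75

[ani]
frag_len = 1020
min_frag_identity = 30.0
min_frag_aln_cov = 70.0

[continuum]
ani_min = 96.0
gcov_min = 90.0
bin_width = 2.0

[pangenome]
min_identity = 50.0
min_coverage = 50.0
inflation = 1.5
n_perm = 20

[replicon_families]
inflation = 1.5

[ks_contrast]
transfer_ratio_max = 0.2
min_chr_ks = 0.1
min_pairs = 10
max_pairs = 10
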