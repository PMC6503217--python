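# Methods

This note documents the models, estimators, defaults and numerical choices
behind the package, and what the synthetic-data validation does and does
not establish about real data.

## The simulator and its study conditions

Genomes evolve forward in time along an ultrametric species tree (Yule
pure-birth by default, birth rate λ = 1 per unit time; any user Newick is
accepted, ultrametric required when pSym transfer is on). The root genome
mirrors the multipartite rhizobial architecture: a chromosome carrying
`n_core_genes` core genes (default 80, the first 58 tagged `ribosomal` as
marker analogs), plus a replicon plan of chromids/plasmids and exactly one
symbiotic plasmid carrying *nodABC*/*nifHDK* analogs; every
extrachromosomal replicon carries its own independently drawn RepC and
RepB genes, so Rep lineages identify replicon families. Genes are random
sense codons (mean 200 codons, sd 15%), separated by neutral spacers that
fill each replicon to its planned length (defaults are desk-scale:
~60 kb chromosome, 25–40 kb plasmids — two orders below real rhizobial
genomes, chosen so the full analysis runs in seconds; all lengths are
config fields).

Substitutions are a Poisson process, JC69: uniform sites, uniform
alternative base, multiple hits allowed; `subs_rate` (default 0.02
substitutions/site per unit branch length) converts time to divergence.
Inside annotated genes, proposals creating an internal stop codon are
rejected (nonsense purifying selection), keeping every CDS translatable;
this deflates within-gene rates by the ~4% of changes that would create
stops and is the only selection in the model. Accessory families arrive
from a finite pool of `n_accessory_pool` uniquely labelled families (gain
rate per absent family) and are lost (rate per present gene; core and
plan genes exempt), giving the equilibrium accessory count
k\* = gain·pool/(gain+loss); long branches are sub-stepped so per-family
event probabilities stay below 0.05 per step. pSym transfer replaces the
recipient's entire symbiotic plasmid with the donor's current copy at
Poisson times over live lineages. A copy genealogy (nodes at every
speciation and transfer) yields the exact expected per-compartment
divergence for every genome pair; with no transfers it provably reduces to
the species tree. One `numpy` generator seeded from `SimConfig.seed`
drives everything; identical configs give byte-identical collections.

A deliberate simplification: a transfer from a *distant* donor makes the
recipient's pSym **older** relative to its close relatives — the truth
matrices reflect this, and tests assert it rather than the naive
"transfer always reduces divergence".

What the simulator does not emulate: recombination within genes,
rearrangements, codon-usage bias, compositional heterogeneity, contig
fragmentation of drafts, and annotation error. Passing tests therefore
demonstrate correctness of the estimators and the pipeline's logic under
the stated generative model, not robustness to those real-data features.

## ANI engine

ANI is fragment-based (JSpecies-style): the query is cut into consecutive
1020 bp windows (truncated at replicon boundaries; trailing fragments
kept); each fragment is placed by exact 15-mer seeds grouped into
32-diagonal bands, and the best-supported band is aligned by infix edit
distance (edlib) in a ±32 band. Identity = (length − edit distance)/length;
fragments are retained at ≥ 30% identity over ≥ 70% aligned coverage
(infix alignment consumes the whole query, so the identity gate does the
work). A placement needs either two distinct seed runs or one run ≥ 32 bp:
a single chance exact match extends past 15 bp only geometrically, so
unrelated megabase pairs retain essentially nothing (measured
G<sub>cov</sub> ≈ 0), while homologous fragments at distances up to ~0.2
seed reliably. Both directed values and their mean (the symmetric ANI used
downstream) are reported, with a match-length-weighted variant alongside;
G<sub>cov</sub> is query-based — the denominator convention is stated
because field usage varies. On simulated JC69 pairs the symmetric ANI
tracks 100·(¼+¾e^(−4d/3)) within ~0.05 percentage points at megabase
scale.

Match registration chains exact shared 15-mers along each diagonal (gap
≤ 200 bp between anchors), on both strands, and registers chains longer
than 300 bp with their percent identity. This finds ungapped local
matches; indels split chains onto new diagonals, which is exactly the
two-flank behaviour wanted for insertion detection. Replicon conservation
is the merged-interval coverage of such matches.

## Orthology, MCL and the consensus core

Protein homology is Smith–Waterman, BLOSUM62, gap open 11 / extend 1
(identity computed over alignment columns; coverage = aligned residues
over each sequence length, or over the larger protein for the 60/60
marker rule — both literal readings of the two gate phrasings). The
BLAST e-value gate is emulated by an empirical noise floor: a Gumbel fit
to 100 shuffled-sequence alignment scores per length bucket, thresholded
at tail probability 10⁻⁶. A 5-mer-sharing prefilter (≥ 3 shared) skips
hopeless alignments on large inputs; at the ≥ 40–50% identity levels the
gates accept, related pairs share dozens of 5-mers, so the prefilter only
removes pairs that could never pass, and it is disabled automatically on
small inputs so oracle comparisons exercise the exact path.

MCL operates on the dense column-stochastic matrix with self-loops at
each node's maximum incident weight, expansion by squaring, inflation 1.5
(config-exposed), pruning at 10⁻⁵, convergence at max-change < 10⁻⁹
(cap 200 iterations, warning on non-convergence); clusters are connected
components of the limit support, which makes the procedure manifestly
node-order invariant. BDBH keeps an edge when best hits (score, then
identity, then lexicographically smallest id — determinism everywhere) are
reciprocal and pass the gates. The consensus core is strict: a family
counts only when a BDBH component and an MCL cluster contain the identical
gene set with exactly one member per genome.

Rarefaction permutes genome order (20 permutations, seeded), takes
medians of core(n)/pan(n), and fits pan to K·n^γ by log-log least squares
and core to A·e^(−n/τ)+C by bounded nonlinear least squares (fallback to a
flat fit when the optimizer cannot estimate a decay, e.g. constant
curves). Symbiotic mapping first deduplicates the reference set by MCL at
the same 50/50 gates, then maps each representative by reciprocal best
hit per genome.

## Phylogenetics

Markers are seeded by the first genome's tagged genes; other genomes
contribute their single qualifying hit (60% identity, 60% coverage of the
larger protein); missing or multi-copy markers are dropped and logged.
Simulator markers are gap-free; unequal-length inputs get an approximate
star alignment to the longest sequence (insertions relative to the
reference discarded) and are flagged as such. Trimming is
complete-deletion by default (any gap/unknown removes the column), with a
gap-fraction mode. Distances are Poisson or Kimura corrections of the
p-distance; saturated pairs (correction argument ≤ 0) are flagged, not
silently dropped, and refuse to enter NJ. The full ML machinery of a
production phylogenomics pipeline (model selection, bootstrapping beyond
the optional column bootstrap, likelihood-based marker scoring) is
deliberately out of scope: distance methods are deterministic, exact on
additive inputs, and sufficient for every downstream use here (the
continuum analysis needs a monotone divergence measure, not a specific
model).

NJ is Saitou–Nei with lexicographic tie-breaking; negative branch
lengths are clamped to zero with the deficit moved to the sister edge
(pair sums preserved), so additive matrices are recovered exactly (RF 0,
lengths to 1e-9). RF is the symmetric difference of canonical non-trivial
bipartition sets, cross-checked against an independent implementation in
tests. The congruence filter builds one NJ tree per marker, takes the
majority-rule consensus, and drops markers whose RF to the consensus
exceeds the 0.75 quantile of the RF distribution — a deterministic
stand-in for recombination/HGT marker screening; with clean markers all
RF values are 0 and nothing is dropped.

## Continuum and cluster calling

Genomic clusters are connected components (single linkage) of the graph
with an edge where ANI > 96 **and** G<sub>cov</sub> > 90, strict
inequalities; whether real cluster definitions intend single- or
complete-linkage is genuinely open, so the linkage is a documented choice
and thresholds are config-exposed. Raising a threshold can only refine the
partition (tested property). The continuum profile is a sliding-window
mean of ANI over genetic distance (window 0.005, half-window steps) — a
fixed-width substitute for local regression that supports the same two
uses, trend and asymptote: windows whose local slope falls below 10% of
the initial slope are flagged saturated. Spearman correlations are
tie-corrected with t-approximation p-values (exact permutation available
for n ≤ 10); p-values are reported, never used for gating.

## Ks and transfer detection

NG86 counts synonymous sites per codon as (synonymous one-step changes)/3
per position (changes into stops count as nonsynonymous), averages
differences over mutational orderings skipping stop-crossing paths, and
applies the Jukes–Cantor correction Ks = −¾·ln(1−4p_S/3); saturated pairs
(argument ≤ 0) are flagged and excluded from medians. The implementation
agrees with an independent reference implementation to 1e-6 in tests. A
known estimator property, characterized in its own test: on
mixed-degeneracy codons the single JC correction treats 2-fold sites
(which saturate slower per counted site) like 4-fold ones, biasing Ks
upward by roughly +4% at 0.2 and +7% at 0.5. Closed-form recovery is
therefore validated on 4-fold-degenerate codon sequences
(Ala/Gly/Pro/Thr/Val/Ser), where the correction's assumption holds
exactly; gene lengths in that validation scale as max(300, 50/Ks) codons
so the integer substitution-count lattice stays fine relative to the
target. A naive third-position JC variant is provided for comparison.

Compartment contrasts pair orthologs by BDBH *within* each compartment
(chromosome with chromosome, pSym with pSym; a gene that moved
compartments cannot pair), codon-align via the protein alignment, and
summarize by medians (robust to saturated and outlier pairs). The
transfer rule — median Ks(pSym)/median Ks(chr) < 0.2 with
median Ks(chr) > 0.1, at least 10 pairs per compartment else
indeterminate — operationalizes the qualitative contrast "pSym Ks near
zero while chromosomal Ks > 0.5"; the chromosomal-Ks guard keeps recently
split strain pairs (both compartments young, comparable histories) out of
the transfer set, and the reverse pattern (pSym ≫ chromosome) is reported
as dissimilar evolutionary lines. The planted-transfer validation uses
chromosomal synonymous divergence 0.5 with transfer ages drawn uniformly
from 2–15% of the split and clonal controls; gene CDSs in that focused
generator evolve synonymous-only (purifying selection on the protein), as
for real conserved core genes — fully neutral evolution at that divergence
would push protein identity below the 50% pairing gate, which is a
property of neutral toy sequences, not of the genes the analysis targets.

## Pipeline determinism

All stages consume one TOML config; every stage logs input sizes,
thresholds and filter-survivor counts to a single stream, and the report
records per-stage counts, thresholds, a SHA-256 manifest of every output
file, and the seed registry. Reruns of an identical config reproduce the
manifest byte-for-byte; this is asserted in tests.

## Known limitations

- The simulator's genomes are orders of magnitude shorter than real
  rhizobial genomes; absolute counts (families, markers) are desk-scale.
- The ANI engine is fragment-based, not maximal-unique-match-based; the
  two agree closely in rank (the weighted variant is provided for that
  check) but absolute values can differ from MUMmer-based tools at high
  divergence.
- The star alignment for unequal-length markers is approximate; real-data
  users with indel-rich markers should supply pre-aligned FASTA.
- NG86's mixed-degeneracy bias (above) means absolute Ks on real genes at
  high divergence carries a few percent of estimator-inherent inflation.
- The homology noise floor is an empirical Gumbel fit, not a calibrated
  Karlin–Altschul statistic; it serves as a noise gate, and the
  identity/coverage thresholds dominate in practice.
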