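# Methods

This note documents the models and procedures `plastevol` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that make
results deterministic.

## Coordinate and format conventions

All internal coordinates are 0-based half-open; GFF3 and the 5-column
annotation TSV (seqid, gene, start, end, strand) use 1-based inclusive
coordinates and are converted at the I/O boundary.  Dated trees are Newick
with branch lengths in million years (myr); ultrametricity is validated with
a tolerance of 1e-6 myr, enough to absorb text-precision round-off while
rejecting genuinely non-clock trees.  N bases are permitted in sequences and
excluded from both numerator and denominator of every GC computation.

## Quadripartite structure and junctions

A plastome is modeled as a circular sequence with four regions in the order
LSC–IRb–SSC–IRa, IRb and IRa exact reverse complements.  Detection finds the
longest pair of disjoint exact reverse-complement repeats of at least
`min_ir_len` (default 1,000 bp, well below real plastome IRs of ~25–27 kb
and above incidental repeats):  exact k-mer seeds (k = 20) are matched
against their reverse complements in the doubled sequence (which linearizes
circularity), each seed is extended maximally, and extensions are
deduplicated on the anti-diagonal invariant (left-occurrence start plus
right-occurrence end is constant under extension), making detection linear
in practice.  Mismatches inside the IR are not tolerated in this version:
real IR copies are homogenized by gene conversion, and the generator emits
identical copies.  Ties between distinct maximal pairs, equal single-copy
regions, or an empty single-copy region are reported as errors rather than
resolved silently.

The genome is canonically rotated to start at the first LSC base; the
partition records the rotation origin so annotated records can be rotated
consistently.  Junctions are J_LB = LSC/IRb, J_SB = IRb/SSC, J_SA = SSC/IRa,
J_LA = IRa/LSC.  Junction profiling measures:

- `psi_rpl22_len` = |rpl22 ∩ IRb| — rpl22 spans J_LB, and the IR duplicates
  its 3' portion to J_LA;
- `psi_ycf1_len` = |ycf1 ∩ IRa| — ycf1 spans J_SA; its duplicated 5'
  portion abuts J_SB from inside IRb;
- `ndhf_jsb_offset` = J_SB − (ndhF's junction-proximal end).  Positive
  values mean ndhF extends into IRb and overlaps the Ψycf1 fragment by that
  many bp; zero or negative values are a gap of that size.  This makes the
  J_SB typing a pure sign test: offset > 0 → overlap type, offset ≤ 0 →
  gap type (a 0 bp gap is a gap).  Whenever |offset| < psi_ycf1_len the
  offset equals the signed Ψycf1/ΨndhF overlap.

A gene annotated entirely outside the regions it should flank yields a 0
with a warning; a missing gene yields a missing field.

## InDel calling, densities, rates

InDels are measured pairwise — each sample against one reference — on the
columns of the supplied multiple alignment.  Each pair is projected first:
columns gapped in both rows carry no information for that pair and are
transparent to run detection (without this, another sample's insertion
columns would artificially split a deletion run).  Terminal gap runs of the
sample row are trimmed as alignment-end artifacts.  A maximal run of
sample-residue-over-reference-gap columns is one insertion; the converse is
one deletion; adjacent insertion and deletion runs stay separate events
(they are not re-interpreted as substitutions).  `ref_pos` is the reference
coordinate of the run's left flank (−1 for an insertion before the first
reference base).

Region assignment uses the reference genome's partition, by left flank;
both IR copies map to the single label IR, and an event flanked by the last
base of a region belongs to that region.  Densities are
1000 · (event bp) / (region length) in bp/kbp, with the IR length counted
over both copies to match the pooling of both copies under one label.
Branch rates divide each tip's assigned bp by its terminal branch duration
(bp/myr).  This version attributes all of a tip's events to its terminal
branch; parsimony placement of shared events on internal branches is out of
scope, so internal-branch rates are not reported — a deliberate narrowing
relative to analyses that number internal branches.

## NG86 dN/dS

Rates use the Nei–Gojobori (1986) counting method under the plastid genetic
code (NCBI table 11), with codon pairs containing gaps or ambiguous bases
masked pairwise (the method requires gap-free codons) and a tolerated,
masked terminal stop.  Synonymous site fractions enumerate the three
alternative bases at each codon position; a change producing a stop codon
counts as non-synonymous, which keeps the site identity N + S = 3 · codons
exact.  Multi-difference codons average the synonymous/non-synonymous step
counts over all orderings of single-base changes, excluding orderings that
pass through a stop codon; if every ordering is blocked, all orderings are
used (the standard fallback; without it the codon pair would contribute no
differences at all).  Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is saturation and the rate is reported
missing, and ω = dN/dS is undefined when dS is 0 or missing.

The high-dS screen ranks genes by mean dS across taxa (missing dS ranks
above every finite value, since it signals saturation) and removes the top
`n_remove` (default 35, which takes a 68-gene plastid set down to 33).  The
threshold is a count, not a dS cutoff, because saturation is relative to
the gene set at hand.

The cross-category test is the tie-corrected Kruskal–Wallis statistic,
H = [12/(N(N+1))] Σ nᵢ(R̄ᵢ − (N+1)/2)² / (1 − Σ(t³−t)/(N³−N)), with a
chi-square upper tail at k−1 degrees of freedom; all-identical values give
H = 0, p = 1.  Implemented from the formula (scipy's version serves as an
independent cross-check in the tests); group sizes of at least 8 keep the
chi-square approximation near its nominal level, which the calibration test
verifies empirically.

## Pn classification

Day/night phase comes from an explicit column rather than clock time (the
photoperiod of a greenhouse run is not knowable from timestamps).  Phase
means are computed per biological replicate first and then averaged (10
replicates by default), so unbalanced sampling cannot bias a call.  The
sign rule is: day > 0 and night ≤ 0 → C3; day ≤ 0 and night > 0 → CAM;
both > 0 → C3-CAM; both ≤ 0 → undetermined.  Ties at exactly 0 resolve to
the ≤ branch.  No significance test is attached — the rule is a
classification, not an inference — and calls are invariant to any positive
rescaling of Pn.

## Climate PCA and group separation

The 19 bioclim variables mix °C and mm, so the PCA standardizes each column
to zero mean and unit variance (correlation PCA) before a singular value
decomposition.  The sign of each loading column is fixed so its
largest-magnitude entry is positive, making output deterministic across
platforms; ranking ties in axis attribution break by variable input order.
Group separation along an axis is the one-way between/within variance ratio
(F-type), calibrated by label permutation (default 999 permutations, p =
(1 + hits)/(n + 1)), because visual separation in a score plot deserves a
number.  WorldClim raster extraction is out of scope; the matrix arrives as
CSV.

## The synthetic-data generator

The generator produces the statistical structure the analyses assume, with
exact ground truth, so every stage is testable without downloads.

**Architecture.**  Random sequence with per-region GC (toy preset:
LSC/IRb/SSC/IRa = 8,000/2,500/1,500/2,500 bp, GC 35.0/43.3/30.5%; fullsize
preset: 84,849/26,300/14,157/26,300 bp, GC 35.08/43.38/30.21% — echoing
real plastome magnitudes), IRa the exact reverse complement of IRb, and the
four bases flanking the IR pair adjusted so the repeat is maximal exactly
at the configured boundaries.  Genes: rpl22 spans J_LB (Ψrpl22 default
39 bp, the observed 37–41 bp range), ycf1 spans J_SA (Ψycf1 default 315 bp,
observed 309–327 bp), ndhF sits at J_SB with a configurable signed offset
(default +10 bp, inside the observed 2–18 bp overlap range).

**Evolution.**  The dated tree defaults to an ultrametric star over 11
species (5 C3, 3 CAM, 3 C3-CAM) with a 10 myr root — terminal-branch rate
attribution is then exact, which is what makes rate-recovery checks
meaningful; arbitrary dated trees are supported, with internal-branch
events inherited by descendants.  Per branch, insertion and deletion counts
are Poisson with mean (bp-rate / mean length) · duration and geometric
lengths (mean 25 bp — simple, heavy-enough tail); category defaults
(insertion 86.53/88.26/92.86, deletion 51.48/93.27/42.73 bp/myr for
C3/CAM/C3-CAM) are genome-wide accumulation rates of the magnitudes the
study system shows.  Substitution rates default to 0.0018–0.0024
subs/site/myr.  Events are drawn in reference coordinates with a one-base
spacing buffer between footprints along any root-to-tip path and never on
the two terminal reference bases: counts are drawn before placement, so
rates are unbiased, while adjacent events can never merge into one run —
the property that makes *exact* event recovery a well-defined contract.
Substitutions apply to present reference bases only, never inside gap
states.  The emitted alignment places insertion columns after their flank
(stable order; independent insertions from different lineages are not
homologous and occupy separate columns).

**Pn traces.**  Plateau amplitudes (day, night) of (+2.0, −0.5) for C3,
(−0.5, +2.0) for CAM, (+1.2, +0.4) for C3-CAM µmol CO2 m⁻² s⁻¹, Gaussian
noise with sd = 0.2·|amplitude|, 10 replicates, samples every 2 h with day
= 06:00–18:00.

**Climate.**  13 localities × 11 species (143 rows) × 19 variables around
subtropical baselines with a shared diagonal covariance.  C3-CAM species
are shifted on bio14/15/17/19 (precipitation seasonality) by 12 column sds;
on the six temperature variables (bio1/5/6/9/10/11) C3 species are shifted
by +0.62 sd and CAM by −5/3 · 0.62 sd, with C3-CAM at baseline.  The
three-level temperature contrast is exactly orthogonal to the C3-CAM
precipitation indicator under the 5/3/3 species split — with two plain
indicators the group proportions force a −0.56 correlation and the leading
PCA axes mix the two variable blocks, so no shift sizes could recover a
clean per-axis attribution.  The sizes come from the block eigenvalue
analysis: the precipitation block's leading eigenvalue is 1 + 3a² ≈ 3.8 and
the temperature block's 1 + 5b² ≈ 3.3 (a², b² the shift's share of a
column's variance), keeping both well above the Marchenko–Pastur noise edge
(≈1.9 at n = 143, p = 19) with an eigengap large enough that sampling
rotation between the two axes stays far from the flip threshold.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: region-specific InDel intensity (real SSCs are
InDel hotspots; implanted events are uniform along the genome), IR gene
conversion and expansion/contraction, codon-aware sequence evolution on the
plastome itself (codon alignments are generated separately, with per-codon
synonymous/non-synonymous change probabilities and a 3× CAM elevation on
clpP/matK/ycf1), spatial autocorrelation among localities, and
non-diagonal climate covariance.  Recovery results on synthetic data
validate the machinery, not the biology.

## Problem sizes and determinism

Tests and the acceptance script run the toy architecture (~14.5 kb, 11
tips) for simulation-heavy checks — 50-seed event recovery, 50-replicate
rate recovery, 100-dataset attribution recovery, 5,000-table Kruskal–Wallis
calibration — and the fullsize architecture for single-genome structure
metrics; these sizes give stable statistics while keeping the whole suite
fast.  Every random draw flows from an explicit integer seed through one
`numpy` generator per operation, so identical seeds give byte-identical
outputs, including the pipeline summary JSON.

## Known limitations

Exact-repeat IR detection can differ by a few bp from published region
tables when real IR copies are not perfectly identical at their ends.
Terminal-only event attribution understates rates on trees with long
internal branches.  The NG86 estimator is a counting method: it ignores
transition/transversion bias and codon frequencies, and saturated pairs are
reported missing rather than extrapolated.  The permutation F-test assumes
exchangeable localities, which spatially clustered records violate.
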