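# Methods

This note documents the statistical model behind `updmr`, the parameters
that matter, the numerical choices, and what the synthetic-data tests do
and do not establish.

## Model and procedure

The unit of evidence is a CpG site with methylated/unmethylated read
counts per sample. Sites are tested for differential methylation, and runs
of consecutive sites are promoted to regions via a combined-probability
statistic.

**Fisher pairwise test.** For two samples the 2×2 table (methylated /
unmethylated × case / reference) is tested with the two-sided
point-probability ("minimum likelihood") Fisher exact test: the p-value
sums the probabilities of all tables with the observed margins whose
hypergeometric probability does not exceed the observed table's (with the
customary 1 + 1e-7 relative slack on the comparison, as in R's
`fisher.test`). A two-sided test is used because regions are called in
both directions. The implementation evaluates vectorised hypergeometric
log-pmfs (`scipy.special.gammaln`) rather than calling
`scipy.stats.fisher_exact` per site, which is ~0.5 ms per table and
prohibitive at genome scale; the two agree to floating-point precision
(unit-tested against scipy and against exact integer enumeration).

**Logistic group test.** For one sample against a group, the model is a
binomial logistic regression of methylation state on a single case/group
indicator. With grouped counts and one binary covariate the ML fit is
saturated at group level (fitted probabilities are the pooled group
fractions), so the 1-df likelihood-ratio statistic is computed in closed
form from binomial log-likelihoods — identical to an iterative GLM fit
(cross-checked against statsmodels in the tests) but orders of magnitude
faster. The LRT is preferred over the Wald test for its behaviour at
small counts. Complete separation (one group fully methylated, the other
fully unmethylated) makes the coefficient estimate diverge; those sites
get a Haldane correction (+0.5 on each pooled cell) and a
`separation_corrected` flag. Quasi-separation needs no correction: the
likelihood, and hence the LRT, stays finite.

**PMD.** Every test also reports the percent methylation difference:
case methylated fraction minus reference fraction, ×100. For group
references the reference fraction is the *unweighted mean of per-sample
fractions*, so a single high-coverage control cannot dominate the effect
estimate (the p-value, by contrast, properly pools reads).

**UP statistic.** If U₁…U_k are iid Uniform(0,1), then
P(∏U ≤ x) = x·Σ_{j<k}(−ln x)^j/j! = Q(k, −ln x), the upper regularised
incomplete gamma function, because −Σ ln U is Gamma(k, 1). The scan
evaluates Q via `scipy.special.gammaincc` with the product accumulated as
a sum of logs; this is stable for x down to 1e-300 and k in the
thousands. Note the tail probability *increases* with k at fixed x: an
extra uniform factor only shrinks the product, so a given x becomes less
surprising.

**Candidate scan.** On each chromosome, every window of ≥ `min_sites`
(default 5) consecutive tested sites qualifies when its first and last
site have p ≤ `alpha_site` (0.05) and its UP probability is ≤
`alpha_region` (0.05). Only windows with significant endpoints can
qualify, so the scanner enumerates significant-site pairs over prefix
sums of ln p — O(s²) in the number of significant sites rather than O(n²)
in all sites. Overlapping or adjacent qualifying windows merge into
maximal regions; the reported UP probability is recomputed over the
merged span. Merging is deterministic and is verified against a
brute-force all-window oracle. No multiple-testing correction is applied
across windows — the region threshold is a plain 0.05, so genome-wide
output should be read as a screening set, not an FDR-controlled one.

**Filters.** Each candidate is split at inter-site gaps >
`gap_max_bp` (200 bp); every fragment is trimmed to significant endpoint
sites and re-tested against the size and UP rules, then kept only if
|mean PMD| ≥ `pmd_min` (20 points) and the first-to-last-CpG span exceeds
`len_min_bp` (250 bp). Splitting (rather than discarding gapped regions)
preserves signal while guaranteeing every retained region satisfies every
rule. Region length is defined by the member CpGs — the evidence span —
not by padded boundaries.

**Intersection.** The final case/control set keeps multi-control DMRs
that a same-direction pairwise DMR overlaps by ≥ `min_overlap_bp`
(50 bp, reusing the only overlap magnitude the protocol states
elsewhere). Coordinates come from the multi-control region; the reported
PMD is recomputed over those coordinates from the designated pairwise
comparison's site results. With a single control the multi-control leg
would duplicate the pairwise one and is skipped (final = pairwise).

**Tissue one-vs-rest.** Each panel member in turn is the target; a site
is tested only if covered in the target and in at least
`min_nontarget_present` non-targets (default panel−1, generalising a
4-of-5 rule for a six-tissue panel). Non-targets enter the logistic model
as one pooled group. Scan and filters are identical to the case/control
analysis.

**Annotation.** Two deliberately different 50-bp rules: tissue-DMR
overlap is per single interval; enhancer-chromatin overlap is summed
across segments in states {3, 8, 9, 10} of an 18-state segmentation.
Gene assignment builds per-transcript regions — promoter window
[TSS−5 kb, TSS+5 kb), strand-aware (on − the window centres on the
transcript end), and body from the promoter's downstream edge to the TES
— aggregates per gene by maximum across transcripts, then walks
categories in precedence order (promoter → body → intergenic) preferring
protein-coding genes within a category, larger overlap, then
lexicographic name. Intergenic regions are linked to the nearest TSS
within 1 Mb (a GREAT-like convenience, labelled intergenic; proper
region-gene enrichment is out of scope). Category precedence outranks
overlap size *and* coding status only within a category — a coding body
hit does not outrank a non-coding promoter hit's category, but within the
promoter category coding wins regardless of overlap size.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_site` | 0.05 | per-site significance for window endpoints |
| `alpha_region` | 0.05 | UP-probability threshold for a candidate |
| `min_sites` | 5 | minimum CpGs per region |
| `pmd_min` | 20 | minimum \|mean PMD\| in points |
| `len_min_bp` | 250 | minimum span (exclusive) in bp |
| `gap_max_bp` | 200 | maximum gap between consecutive member CpGs |
| `min_overlap_bp` | 50 | intersection / tissue / enhancer overlap floor |
| `min_coverage` | 1 | reads required for a site to count as present |
| promoter window | ±5 kb | gene-assignment promoter region |
| enhancer states | 3, 8, 9, 10 | enhancer classes of the 18-state model |

All thresholds are plain data (`DmrParams`) and surfaced end to end; the
defaults are the published protocol's values. `min_coverage` defaults to
1 because the protocol states no floor; users with deep methylomes may
want 5–10.

## Synthetic data: the stated world

`generate_methylome_panel` simulates CpGs in clusters (geometric
within-cluster gaps, mean ≈ 20 bp; geometric between-cluster gaps, mean
≈ 1.5 kb), a blockwise methylation landscape shared by all samples
(block means Beta(8,2) → ~80% genome-wide methylation with hypomethylated
blocks, geometric block length ≈ 50 sites, per-site jitter sd 0.03),
negative-binomial coverage (mean 30, dispersion 0.2 — so a few sites drop
to zero coverage and exercise the absence paths), and binomial methylated
counts. Planted regions shift the methylation probability of designated
samples by delta at an evenly spaced run of sites and are recorded in a
truth table. With the default planted effect (|PMD| = 40, 10 sites /
500 bp), the full chain recovers ≥ 90% of regions with no false calls in
~2×10⁵ null CpGs (acceptance suite, 20 seeds), and |PMD| = 10 effects are
eliminated by the ±20-point filter.

What the generator does **not** emulate: bisulfite-conversion error,
strand asymmetry, spatially correlated coverage dips, copy-number or SNP
confounders, or correlated methylation noise between neighbouring sites.
A green recovery test therefore shows the statistical chain is correct on
data matching its own model — not that the thresholds are optimal for
real methylomes.

## Numerical choices

- Products of p-values are carried as sums of logs; site p-values are
  floored at 1e-300 and region UP probabilities at the smallest
  subnormal, keeping every reported probability in (0, 1].
- The Fisher implementation sorts the included table probabilities before
  summing, making swap-of-groups symmetry exact to the last bit.
- LRT statistics are clamped at 0 before `chi2.sf` (tiny negative values
  can arise from cancellation when the groups are identical).
- Cross-sample 1-bp coordinate reconciliation merges only isolated pairs
  in the position union; runs of ≥3 consecutive coordinates are ambiguous
  and left unmerged, and a pair occurring *within* one sample (a CpCpG)
  is kept as two sites with a warning.
- All randomness flows through explicit `numpy.random.default_rng`
  seeds; reruns are byte-identical, including written BED output
  (floats serialised with `%.17g`, read back with round-trip parsing).

## Known limitations

- The chi-square approximation to the logistic LRT is calibrated at
  moderate methylation levels (measured null rejection 0.051 at 70%
  methylation, 30× coverage) but grows anti-conservative toward the
  extremes (≈ 0.067 at 90%); Fisher has no such issue but is only
  pairwise.
- At coverage below ~10 reads the discrete Fisher test and the asymptotic
  LRT can order extreme sites differently; their ranking agreement
  (ρ > 0.99) is established for totals of 10–30 reads.
- No FDR control across regions, matching the protocol being
  reimplemented.
- Coverage-anomaly detection (a sample's regional mean coverage below a
  quarter of its genome-wide mean over a final DMR) only flags; no
  automatic fallback to the pairwise call is attempted.
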