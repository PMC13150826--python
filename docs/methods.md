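# Methods

`uvpdfy` analyzes native-MS / 193 nm ultraviolet-photodissociation (UVPD)
experiments that probe conformer-selective metal binding to an intrinsically
disordered protein, with human α-synuclein (UniProt P37840, 140 residues) and
Zn²⁺ as the bundled default system. The pipeline consumes *deconvoluted*
per-scan fragment lists (neutral monoisotopic masses, e.g. TopFD-style
msalign output) and centroided precursor peak tables; it does not touch raw
or profile spectra.

## Fragment chemistry

Residues are 1-based; cleavage site *i* is the backbone bond between
residues *i* and *i+1*, so the N-terminal fragment spanning 1..*i* and the
C-terminal fragment spanning *i+1*..L at the same site are complementary.
Twelve ion series are modelled — N-terminal a, a+1, a+2, b, c and C-terminal
x, x+1, y, y−1, y−2, z, z+1 — with neutral masses expressed relative to the
summed residue masses of the span:

| series | offset |
|---|---|
| b | 0 |
| a | −CO (−27.994915 Da) |
| c | +NH₃ (+17.026549 Da) |
| y | +H₂O (+18.010565 Da) |
| x | y + CO − H₂ |
| z | y − NH₃ + H (z-radical) |

Satellites (±k) shift their base series by k hydrogen atoms (±1.007825 Da
each), the hydrogen-transfer products characteristic of photodissociation.
These offsets live in one table (`sequence.ION_SERIES`) and the underlying
element/residue constants ship as versioned TSVs (`data/elements.tsv`,
`data/residues.tsv`), so the whole mass scale is inspectable and
replaceable without code changes.

Zn²⁺ adducts: the default per-zinc neutral delta is Zn − 2H
(+61.913492 Da), the charge-compensated form typical of native metal
binding; bare Zn addition (+63.929142 Da) is selectable
(`AdductConvention`). The convention in force is recorded in every run
manifest. The theoretical database enumerates one species per
(series × site × zinc count), i.e. |series| × (L−1) × (max_zinc+1)
entries — 5 004 for α-synuclein with all 12 series and up to 2 zincs.

## Isotope model

Theoretical isotope patterns are computed by per-element convolution of
single-atom distributions, aggregated by nominal neutron shift (binary
exponentiation over atom counts; per-bin masses are abundance-weighted
expectations). Fine structure is deliberately not resolved — 50k-resolution
fragment spectra only see the aggregated envelope. Peaks below
`prune_threshold` (default 0.01) of the base peak are pruned (never the
base peak itself), and a fixed numerical floor of 1e−45 relative abundance
guards against double-precision underflow in very large compositions.
Observed envelopes are scored by Pearson correlation against the
theoretical pattern after nearest-mass alignment within 0.02 Da;
theoretical peaks without a partner pair with zero intensity. Scores are
undefined (and the ion fails the reliability filter) when fewer than two
pairs align or either vector has no variance.

## Matching and filtering

Each deconvoluted mass is matched against every database species within a
two-sided relative tolerance of 2×10⁻⁶ of the theoretical mass. Ambiguity is
resolved deterministically: smallest |relative error|, then higher envelope
correlation, then base series before satellites (fixed priority list), then
lower zinc count. Rejected candidates are retained on the match record.
Charge states of one fragment within a scan are summed as one chemical
species. Per replicate, a species is *kept* when detected in ≥16 of 20
scans and, where envelopes exist, its mean envelope correlation exceeds
0.7; feature tables without envelopes skip the correlation filter with a
logged warning. The per-species intensity summary across scans is the
median over detected scans (robust to per-scan fluctuation; the mean is a
near-identical alternative we did not expose). If the median signed mass
error of a replicate exceeds 0.5×10⁻⁶ a warning suggests recalibration;
no automatic recalibration is applied.

## Normalization, FY, ΔFY

Replicate intensity columns are median-normalized on the species detected
in all replicates (each column scaled to the grand median of the
per-column medians). The fragment yield at site *i* is
FY(i) = 100 × Σ intensity(a, a+1, a+2, x, x+1 at site i) / Σ intensity(all
kept species), with holo and apo variants of a species pooled by site;
FY values therefore sum over sites to ≤100 (percentage points). Sequence
coverage is the percentage of the L residues whose cleavage site carries
any kept species — the denominator is L, under which 134 covered sites of
a 140-residue protein report 95.71 %.

ΔFY(i) is the mean FY difference (metal-incubated − apo) tested site-wise
with a two-sample t-test; sites with P ≤ 0.001 are significant, and region
summaries (Nterm 1–60, NAC 61–95, Cterm 96–140) average ΔFY over
significant sites only. Sites absent from one condition enter as FY = 0 so
every covered site is testable. Two degenerate-case rules: when both
conditions have zero variance, equal means give P = 1 and unequal means
P = 0 (a difference with no scatter); sites absent everywhere are simply
Δ = 0, P = 1.

**t-test flavor.** The default is the pooled-variance Student test;
Welch is selectable (`t_test="welch"`). With the usual three replicates
per condition, Welch–Satterthwaite degrees of freedom collapse toward 2,
where two-sided P ≤ 0.001 requires |t| ≳ 30 — a threshold that even
thirty-standard-error effects fail routinely, leaving the significance
rule practically inert. The pooled test (df = 4, critical |t| ≈ 8.6) keeps
the stated threshold meaningful for balanced designs and is the plain
reading of an unqualified t-test. No multiple-testing correction is
applied by default (the P ≤ 0.001 rule is used as-is); a
Benjamini–Hochberg mode can be layered on the returned p-values by the
caller.

## Holo analysis

Holo (zinc-retaining) fragments are all kept species with zinc_count ≥ 1
across all twelve series. Same-terminus fragments at the same site are the
same holo fragment: the set collapses to unique (terminus, site) pairs with
pooled intensity. Terminus counts (Nterm = a/b/c-family species,
Cterm = x/y/z-family) and their sum summarize each conformer. Holo/apo
intensity ratios per (terminus, site) pool the same way; apo-zero sites
with holo signal are flagged infinite rather than dropped.

## Charge-state-distribution model

Precursor peaks are assigned to expected m/z positions
(M + n·Δ_Zn + z·1.007276)/z within 10 ppm (nearest position; exact ties to
lower zinc count, then lower charge) to build a (charge × zinc-count)
intensity profile. `ChargeStateMixtureModel` fits
Σₖ Aₖ·exp(−(z−μₖ)²/2σₖ²) to the per-charge totals (apo+holo summed;
discrete charges, no interpolation) by bounded nonlinear least squares
(lmfit/Levenberg–Marquardt), initialized at μ = (7, 10, 13), σ = 1.5, with
σ ∈ [0.3, 5] and μ inside the charge range. Non-convergence flags the
result instead of raising. Subpopulation fractions are component areas
Aσ√(2π) normalized to 1; zinc-stoichiometry profiles at a charge are the
intensity vector over zinc counts normalized to its own sum. Note that at
any single charge this profile is the *blend* of all conformer components
weighted by their Gaussian densities there, not a pure component profile.

## Synthetic experiments

The generator plants ground truth for every stage and writes the same text
dialects the readers consume, so the pipeline is testable end-to-end
without instrument data. Study-structure defaults: 20 scans per replicate,
3 replicates per condition (apo and Zn-incubated), per-scan intensities =
truth × mean-one lognormal noise (σ = 0.2) thinned by Bernoulli detection
(p = 0.9), precursor intensities with σ = 0.05 lognormal noise
(high-resolution precursor signals are far more reproducible than per-scan
fragment intensities). Everything is deterministic given the seed.

Each covered site carries a/a+1/a+2/x/x+1 species splitting the site's FY
budget 30/25/10/20/15 — an a/x-rich spectrum as 193 nm UVPD produces —
plus b/y species carrying the non-FY budget evenly, so planted per-site FY
values hold exactly by construction. Splitting the FY budget over all five
series also keeps the 16-of-20 filter's knife edge (a species at
detection 0.9 survives a replicate with probability 0.957) from letting a
single species loss dominate replicate FY variance. At planted holo sites
the site's species split into an apo part and a zinc-retaining part
(holo fraction 0.5, zinc count = the conformer's dominant stoichiometry).

Three presets mirror the conformer designs of the bundled system. Shared
CDS: components at 7+/10+/13+ (σ = 1.2) with weights 0.40/0.35/0.25 and
zinc-stoichiometry profiles peaking at n = 3, 1 and 2 respectively
(weights and widths are not constrained by published values; they were
chosen once as plausible native-MS settings). Per preset: covered-site
counts 119/134/130 (⇒ coverages 85.00/95.71/92.86 %); changed-site counts
and per-site FY drops per region chosen so the count-weighted means land
at the designed region/overall ΔFY values (low: −1.81/−1.48/−1.48,
overall −1.69; intermediate: −0.92/−1.41/−0.46, overall −0.95; high:
−0.93/−0.98/−0.73, overall −0.93); holo (terminus, site) maps sampled from
the designed ranges with counts 6/31, 34/55 and 40/13 (N/C). Unperturbed
covered sites sit at 0.15 pp FY; changed sites retain 0.5 pp after binding
(binding suppresses but does not abolish cleavage), which keeps the summed
FY budget under 100 and the planted effects detectable at the study's
noise level. Site realizations are re-sampled per seed within the designed
ranges.

What the generator does *not* emulate: intensity-dependent detection,
correlated noise across scans, chemical noise and false deconvolution
artifacts, mass-error drift, internal fragments, and oligomer precursors.
Passing the recovery tests therefore shows the pipeline's statistics and
bookkeeping are correct under a faithful intensity/dropout model — not
that real spectra of comparable quality will yield the same power.

## Numerical and procedural choices

- Matching tolerance is relative to the theoretical mass, two-sided.
- Replicate pooling for coverage and holo counts uses the union of kept
  species across replicates (a species kept in any replicate counts),
  the sensitivity-maximizing analogue of manual curation of borderline
  ions; per-replicate tables are also emitted.
- Median normalization requires at least one species detected in all
  replicates; otherwise it is skipped with a warning rather than failing
  the run.
- The CDS fit treats charges as discrete abscissae; rescaling all
  intensities rescales amplitudes only.
- Seeds: every stochastic step (generator, site realizations) derives
  from the single user seed; derived seeds stay below 2³¹.

## Problem sizes used in the shipped checks

Test and acceptance runs use the full 140-residue sequence, the complete
12-series database (5 004 species at max_zinc 2, 6 672 at 3), 20 scans ×
3 replicates × 2 conditions per experiment, and 20 seeded repetitions of
the three presets for the recovery property. These sizes exercise every
code path at full protein scale while keeping a complete run of the suite
in the minutes range.

## Known limitations

- No systematic mass recalibration; a drifted dataset is flagged, not
  corrected.
- The envelope correlation assumes centroided envelopes; profile traces
  must be centroided upstream.
- Internal fragments, side-chain losses and PTMs other than the metal
  adduct are out of scope.
- Holo terminus counts depend on the deduplication rule; species-level
  counts before deduplication are available from the evidence tables.
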