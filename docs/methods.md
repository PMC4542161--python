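# Methods

## Scope and model

The pipeline analyses a two-group (HFD steatosis control vs STAM NASH model)
× two-age (8, 12 weeks) liver lipidomics design with n = 5 animals per cell.
Inputs are identified-species peak tables; peak detection, alignment and
species identification are upstream of this package and taken as given via
the catalogue. All group inference is rank-based and per-unit (species,
class total, pathway mean); no between-unit correlation model is fitted.

## Nomenclature and catalogue

Species names follow the `<total carbons>:<total double bonds><class>`
shorthand with optional `e/p` (ether/plasmalogen) infix and `-a`/`-b` isomer
suffix. Class tokens are matched longest-suffix-first so `HexCer` is never
mis-parsed as `Cer` and `38:5e/pPC` resolves to class PC with the ether
flag. Isomer suffixes denote chromatographically resolved species of one
formula and are always distinct catalogue entries.

Chain-accounting validation checks, for every determined chain set, that
chain carbons sum to the shorthand carbon total and that chain double bonds
plus one per plasmalogen (`p`) chain — ether (`e`) chains add zero — sum to
the shorthand double-bond total. The convention is fixed by the assigned
ether species in the packaged panel (e.g. `36:5e/pPE = 16:0p/20:4`:
16+20 = 36 and 0+4+1 = 5). Chain sets containing a sphingoid base (`d`) are
exempt from the sum checks: in this shorthand dialect the sphingolipid
totals do not reliably equal base + N-acyl sums (the catalogue carries a
38:1 ceramide assigned d18:1/16:0), so enforcing the rule there would
reject measured assignments.

The packaged reference catalogue reproduces the study census exactly — 250
species in 18 classes; 103 phospholipids, 16 sphingolipids, 112 neutral
lipids, 11 free fatty acids, 8 acylcarnitines — and is verbatim for the 62
assigned PC/PE panel rows. Species outside the published panels are
structurally valid placeholders (`source=placeholder`): their names, classes
and ion modes are realistic, but they are stand-ins, and analyses that
depend on specific chain assignments are meaningful only for the panel
species.

## Normalization

Normalization is a per-sample ratio to the matched internal-standard
channel; standards are spiked into the homogenate before extraction, so they
index per-sample recovery and response. Routing is by category and ion mode
with a class-level override for cardiolipin (positive mode, shares the TG
standard with the neutral lipids). No cross-sample scaling, drift or batch
correction, or imputation is applied. Zero species intensities are accepted
as true zeros (absent peaks); a zero or negative standard intensity is a
hard error naming the sample, because the ratio is then meaningless.
Normalized values are scale-invariant per sample: multiplying an entire
sample column (species and standards alike) by any c > 0 leaves them
unchanged.

## Exact Mann-Whitney test

With m and n per group, the two-sided p-value is computed by full
enumeration of all C(m+n, n) labelings of the pooled values: mid-ranks are
assigned once to the pooled sample (ties therefore handled inside the
enumeration), U = min(U_a, U_b) is the min-convention statistic, and
p = P(min-U ≤ observed min-U) under the uniform labeling null. Identical
groups give p = 1; complete separation at 5 vs 5 gives p = 2/252. Half-point
U values arise with ties; the ≤ comparison uses a 1e-9 slack to absorb
floating-point rank sums. Above 50,000 labelings (never reached at this
design) the implementation falls back to the tie-corrected,
continuity-corrected normal approximation.

Because the null distribution is discrete, the test's achievable size at
n = 5 vs 5 is not 0.05 but 8/252 ≈ 0.0317 (the largest attainable level
below α); calibration checks therefore compare the empirical null rejection
rate against this exact size, not against α itself, and additionally require
it to stay below α. Direction calls (increased/decreased at p < α by group
means; equal means flagged `tied`) use the per-test α = 0.05 with no
multiplicity correction, matching the per-test significance convention of
the study design; a Benjamini–Hochberg q column is emitted for reference
only. Fold changes are ratios of arithmetic group means; log2 values are
exported alongside for display.

## Composition statistics

Within-class percentages are computed per sample (100 × species / class
total) and then averaged over the group's samples, rather than as ratios of
group means; the two differ in general, and the per-sample form was chosen
for consistency with the per-sample rank statistics and for its exact
invariance to per-sample rescaling. Percent change is the signed
percentage-point difference (contrast minus reference); the notable-mover
filter keeps |change| > 1 percentage point, sorted by magnitude.

Side-chain fractions for a two-chain glycerophospholipid class divide the
multiplicity-weighted sum of species values by twice the class total, per
sample, then average within the group. Multiplicity weighting — a
homo-diacyl species such as 16:0/16:0 counts twice for 16:0 — is the only
weighting under which fractions over all acyls sum to 1 given fully
assigned chains, which is why it is the default; a `presence` weighting
(species counted at most once) is available behind a switch since the
alternative convention cannot be excluded. Species with several alternative
chain sets distribute their value equally across alternatives; species with
unassigned chains (`n.d.`) contribute to the denominator only, and the
unassigned remainder is reported as an explicit `undetermined` row so
columns always total 1. Ether and plasmalogen chains match an acyl key by
their printed carbons:double-bonds label (16:0p matches 16:0); sphingoid
bases never match (they are not acyl side chains).

## Eicosanoids

The targeted panel is normalized to leukotriene B4-d4 (peak areas) and
expressed, per sample, relative to arachidonate; the standard cancels in the
ratio, so ratio-view results are identical from raw or normalized areas.
Pathway membership (PGD2, TXB2, 12-HHT → COX; 5-HETE → LOX; 18-HETE → CYP;
arachidonate → precursor) is a total partition. Pathway-level group tests
run on per-sample pathway-mean ratios (`pathway_means`): averaging a
pathway's members damps metabolite-specific noise while keeping the shared
precursor denominator, and it tests the actual claim — about the pathway —
rather than requiring every member to clear significance individually,
which at n = 5 discards substantial power for multi-member pathways.

## Synthetic-data generator

The generator emulates the study skeleton: per-species baseline medians
drawn log-uniformly over 10^3–10^5 (arbitrary intensity units; real
between-class scales are unknown and irrelevant to rank statistics),
multiplicative log-normal sample noise with 20% CV, internal-standard
channels at a nominal 1000 with independent 10% CV, and multiplicative
effects on classes, fatty acyls within a class, or eicosanoid metabolites.
Fatty-acyl effects scale a species by effect^(k/2) with k its matching-chain
multiplicity, so paired down/up effects (the `sidechain8w` preset: 16:0 ×0.5
and 18:0 ×2 in PC and PE) shift composition while approximately preserving
class totals, mimicking side-chain remodelling without class-level change.
Presets encode the reported directions: `nash8w` (SM/Cer/CoQ ×2.5, DG/TG
×0.4 in the 8-week STAM cell), `fibrosis12w` (Car ×2.5 at 12 weeks vs 8
weeks within STAM), `sidechain8w`, and the eicosanoid `cox8w` preset
(arachidonate, 5-HETE and 18-HETE ×0.5 with COX products untouched, so COX
ratios double while LOX/CYP ratios are unchanged). Identical seeds produce
bit-identical files; the CLI requires an explicit seed.

What the generator does **not** emulate: correlation between species (real
co-regulation within classes and shared-precursor structure), heavy-tailed
or heteroscedastic noise, missingness/censoring at the detection limit,
batch or drift structure, and real intensity scales. Passing recovery tests
therefore demonstrates that the pipeline's statistics detect the programmed
effect structure at the study's sample sizes and noise level — not that
those effects are detectable in any particular real dataset.

## Problem sizes and numerical choices

Default analyses run the full 250-species catalogue at n = 5 per cell.
Calibration uses 200 simulated null studies (50,000 species-level exact
tests); recovery experiments use 100 seeded studies per preset. Tables are
written as UTF-8 TSV with `%.10g` floats (round-trip stable); ragged rows
and duplicate identifiers are hard parse errors with line numbers; Windows
line endings are accepted. The pipeline computes every artifact in memory
before writing, so a failing run leaves no partial bundle.

## Known limitations

- Placeholder catalogue entries make whole-catalogue analyses structurally
  faithful but not species-exact outside the published PC/PE panels.
- The exact test's discreteness makes nominal-α error rates unattainable at
  n = 5; reported significance is conservative (size ≈ 0.032 at α = 0.05).
- Composition percentages assume no systematic within-class ionization bias
  change between groups (percent of summed signal, not of molar amount).
- The eicosanoid panel is fixed to six analytes by default; other panels can
  be supplied but have no packaged pathway map beyond the COX/LOX/CYP split.
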