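# Methods

## The measurement model

A GC-EI-MS fragment of a TMS derivative carries a subset *S* of the parent
metabolite's backbone carbons together with derivatization atoms (C, H, N, O,
Si). Its measured isotopic cluster at nominal masses M0..Mn (n = |S|) mixes
three independent sources of mass shift:

1. the ¹³C labeling signal on the backbone carbons in *S* (the carbon
   isotopologue distribution, CID);
2. natural isotopes of every non-backbone atom (¹³C of derivatization
   carbons, ²H, ¹⁵N, ¹⁷O/¹⁸O, ²⁹Si/³⁰Si);
3. in tracer experiments, two backbone terms: natural ¹³C on carbons the
   tracer did not label (mass surpluses, Binomial(n−j, 0.011)) and ¹²C
   impurity on carbons it did (mass deficits relative to j, modeled as
   Binomial(j, purity) actually-heavy carbons with purity 0.99).

The predicted cluster of the pure j-labeled isotopologue is therefore the
convolution of the per-atom natural-isotope shift distributions of all
non-backbone atoms with the two backbone binomials (or with a delta at j when
backbone corrections are off, the correct mode for isotopic standards whose
¹²C/¹³C pattern is fully controlled). Stacking these predictions as columns
gives the per-fragment correction matrix **M**; the CID is recovered from raw
areas *r* by solving **M**x ≈ *r* with x ≥ 0 (scipy's NNLS) and normalizing x
to sum 1. NNLS is used instead of matrix inversion because inversion can
return negative fractions on noisy clusters; the relative residual of the fit
is kept on the result and is worth inspecting when it exceeds ~1e-3 on
synthetic data. The measured window is exactly M0..Mn; longer input clusters
are rejected rather than silently truncated, and both the simulator and the
matrix builder truncate the same untruncated convolution, which is why
noiseless round trips are exact to machine precision.

The fractional mean ¹³C enrichment of a fragment is Σᵢ i·Mᵢ / n. Under the
tracer-mode correction, unlabeled material corrects to 0% and a backbone
fully labeled by a 99%-pure tracer corrects to 100%.

## Positional enrichment by fragment combination

The mean enrichment of a fragment equals the arithmetic mean of the
per-position enrichments over its backbone subset. Fragments sharing part of
a backbone therefore give linear access to single positions; e.g. for a
three-carbon metabolite, E(C1) = 3·E(C1C2C3) − 2·E(C2C3). All published
combinations for the six supported metabolites are encoded with exact
`Fraction` weights, and each is verified symbolically at construction:
substituting arbitrary per-position values through the membership vectors
must reproduce the target position exactly, so a wrong weight cannot survive
import. Chained definitions (malate C3 via the already-derived C4; serine
method B's C2 via its C1 and C3) are flattened to direct fragment weights,
with the chain recorded in the spec's notes.

Two printed forms of the source equations are algebraically inconsistent
with the mean-of-positions model and are implemented in their consistent
orientation (the serine method-B C1/C3 pair, whose printed right-hand sides
isolate each other's position, and the malate C3C4 intermediate); the
symbolic check enforces this. The alanine whole-molecule line is implemented
as (E_C1 + 2·E_C2C3)/3, the only reading consistent with the model.

Each combination carries the verdict from the standard-based evaluation:
**validated** — glycine C1 (via the C2 fragment at m/z 174, 100 or 86);
serine C1, C2, C3; malate C1 (via m/z 335 or 245); glutamate C1 via the 246
fragment — or **biased** (alanine C2/C3, malate C3/C4, glutamate C1 via 156,
proline C1, the latter for variability rather than inaccuracy). Positional
values are computed per replicate and then summarized, never on averaged
enrichments, and out-of-range values (possible because the weights amplify
fragment biases) are flagged, never clipped. No normalization to a t = 0
baseline is applied anywhere: several fragments are inaccurate at natural
abundance, and dividing by a biased baseline would distort every later time
point.

A generic least-squares solver handles arbitrary fragment sets: the design
matrix has one row per fragment with 1/|S| on its member positions; a
position is reported identifiable when no null-space direction of the design
touches it (tolerance 1e-10 on null-space components).

## Validation against binomial standards

¹³C-PT standards contain every positional isotopomer in equal proportion, so
each n-carbon fragment has the Binomial(n, ½) CID — after rescaling by 2ⁿ,
the integer Pascal row — and every position sits at exactly 50% enrichment.
The validation report compares each measured isotopologue fraction, fragment
mean enrichment and positional value with its expectation through the 95%
interval mean ± 1.96·SD/√k over k replicates. Two numerical choices: the
sample SD uses the k−1 denominator, and the z-factor 1.96 is used verbatim
rather than a t-quantile (for k = 4 the t-based interval would be ~1.6×
wider), reproducing the published arithmetic exactly; with small k this
interval is anti-conservative, so isolated flags on noisy but unbiased data
are expected (about 14% per quantity at k = 4) and only systematic flags are
meaningful. A 1e-9 guard band keeps machine-precision round-off on noiseless
data from being flagged.

## The simulator and what it does (not) emulate

The forward model shares the isotopologue-pattern code with the correction,
so each mirrors the other by construction; correctness of both is
established against *independent* oracles (exhaustive enumeration of isotope
assignments for small formulas, exact-rational polynomial expansion via
sympy for every registry formula) rather than against each other alone.

Ground truth is a `LabelState`: independent per-position labeling
probabilities (fragment CIDs are then Poisson-binomial) or an explicit
distribution over all 2^N positional isotopomers (CIDs by marginalization).
Three designs are built in:

- **PT standards**: p = 0.5 at every position, four replicates, standards
  correction mode;
- **tracer kinetics**: a light/dark × {0, 1, 2, 4, 6 h} × 4-replicate course
  encoding the qualitative biology the method resolves — serine and glycine
  label only at C2 and only in the light (GDC/SHMT photorespiration,
  reaching p = 0.18 at 6 h), glutamate C1 rises in the dark only (TCA second
  turn, p = 0.06 at 6 h), malate C1 = C4 behaves similarly in both
  conditions (PEPc/fumarase vs TCA), alanine labels uniformly as the
  pyruvate proxy, and everything starts at natural abundance at t = 0. The
  labeling magnitudes are plausible leaf-disc incorporation levels chosen
  once for the scenario; they are not fitted to any measured kinetics.
- **contaminant injections**: a co-eluting ion at a configurable m/z offset
  and intensity (optionally with its own natural isotope pattern), covering
  the two documented bias classes — cluster overlap from co-elution (the
  proline 216 / isoleucine 218 case) and isobaric contamination at M0 (the
  glutamate/malate m/z 117 case). Intensities are user-set knobs: the real
  plant-matrix biases (e.g. malate C2C3 reading 0.36 at t = 0) have no
  published generative explanation, so the simulator reproduces their
  direction and propagation, not their exact magnitudes.

Noise is multiplicative log-normal per cluster mass with a given CV
(area-proportional error being the dominant GC-MS regime), mean-one so
expected areas are unbiased; replicate seeds are derived from the master
seed through `SeedSequence`, making every dataset reproducible. The
simulator does not model chromatographic peak shape, detector saturation,
derivatization-efficiency drift, or fragmentation-pathway changes — passing
tests demonstrate the correctness of the computational chain under its own
stated assumptions, not instrument-level accuracy on real extracts.

## Statistics in the pipeline

Condition comparisons use the two-sided Wilcoxon–Mann–Whitney test: exact
enumeration when both groups have ≤ 8 tie-free values (the four-vs-four
design's floor is p = 2/70 ≈ 0.0286), otherwise the tie-corrected normal
approximation with midranks. A Shapiro–Wilk normality check is logged per
group as context for preferring the rank test, but the comparison used is
always rank-sum. No multiple-testing correction is applied, matching the
original procedure; users needing familywise control should apply it to the
output table. Zero-area clusters are dropped with a warning rather than
propagated as NaN.

## Problem sizes and defaults

Default isotope abundances: H 0.999885/0.000115, C (1−a)/a with a = 0.011,
N 0.99636/0.00364, O 0.99757/0.00038/0.00205, Si 0.9223/0.0467/0.0310; the
¹³C value is a single overridable parameter. Tracer purity defaults to 0.99.
Simulated datasets use four replicates and a total cluster area of 1e6
counts; the shipped kinetics scenario has 40 samples (2 conditions × 5 time
points × 4 replicates) across all six metabolites, which runs the full
pipeline in a couple of seconds.

## Known limitations

- Low-resolution (nominal-mass) correction only; isobaric contaminants under
  a cluster are indistinguishable from labeling without accurate mass.
- The registry's two published formula/mass mismatches are resolved by
  documented working values (proline 142 → C7H16NSi; glutamate 245 → M0
  246); the published values are preserved for audit, and the glycine C2
  fragment at m/z 248 coexists with the text's m/z 174 ion without a
  published reconciliation.
- The mean-of-positions model assumes fragment formation does not
  discriminate isotopomers; a position-dependent fragmentation bias would
  violate the combination identities and surface as a standards-validation
  flag, not be corrected.
- Neutral-loss masses in the registry are informational; one published loss
  (malate "TMS-OH, CH₃" given as 90 where the mass difference is 105) is
  kept verbatim.
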