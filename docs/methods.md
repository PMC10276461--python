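# Methods

## Scope and model

glyscreen identifies released, reducing-end-labeled N-glycans by accurate
mass. It does not score or rank candidate structures: an identification is a
database mass found in the data within tolerance, optionally corroborated by
MS2 fragment evidence. All masses are monoisotopic; isotope envelopes,
average masses and charge states above 4 are out of scope.

The mass conventions are:

* residue mass = free monosaccharide mass − water; a chain of residues plus
  one water is the free glycan.
* the tabled fluorescent-tag mass (2-AB 138.0793 Da, procainamide
  237.1841 Da) includes both that terminal water and the net +2H of
  reductive amination, so labeled mass = Σ residues + tag. A "custom" tag of
  18.0106 Da (one water) expresses an unlabeled glycan.
* proton mass 1.007276 Da (not the hydrogen atom mass): m/z arithmetic must
  be ppm-accurate. +Na/+K adducts substitute the metal cation (22.98922 /
  38.96316 Da) for one charging proton.
* the "−OH" adduct is implemented as a neutral hydroxyl loss (17.00274 Da)
  before protonation, read literally from the hydroxyl; a "−H2O" variant
  (18.01056 Da) is selectable for instruments/workflows that report water
  loss instead.

Monosaccharide codes are 3-letter (Xyl, Fuc, Gal, Man, Hex, GaN, GlN, HeN,
NAN, NGN). Gal/Man/Hex and GaN/GlN/HeN are distinct codes sharing one mass;
everything downstream that reasons about isomers compares masses (rounded to
4 decimals), never codes. The registry is extensible from a CSV of
(id_code, formula) rows; masses always derive from formulas.

## Fragment enumeration

A glycan is a rooted tree; the root is the tagged reducing end. The engine
enumerates connected subtrees directly (for each candidate top node, every
way of including/excluding child branches) rather than iterating over edge
subsets; the number of boundary edges of a retained set *is* the minimal
number of cuts that produces it, so the result is provably identical to
brute-force enumeration over all edge subsets of size 1..max_cuts with
retained-set deduplication — the test suite checks this equivalence against
an independent brute-force oracle on random trees. Classification: contains
root → Y; one boundary cut → B; otherwise internal. The intact parent is
excluded. max_cuts defaults to 7; for small trees the effective bound is the
edge count.

The tag–glycan bond is not cleaved by default (every fragment contains at
least one sugar); a `cleave_tag_bond` switch adds the bare-tag Y0 ion for
workflows that observe it. Linkage annotations (e.g. `[a1,3]`) are carried
as labels and never affect mass — linkage isomers are mass-identical by
construction. The on-disk fragment database stores (mass, ion class,
residue multiset); retained node sets are an in-memory detail that matching
does not need.

"Qualifying" fragments — the denominator of the percent-identified
statistic — are fragments of ≥ 2 residues whose rounded mass occurs exactly
once within the parent's own fragment set; single residues and
mass-degenerate pieces carry no discriminating information.

## MS1 search

Defaults: 10 ppm tolerance, procainamide tag, max charge 2, relative
intensity threshold 25 %, RT interval 0.25 min (only when the database
supplies expected RTs). The m/z window half-width is center·ppm·10⁻⁶ for ppm
tolerances and value/z for Da tolerances.

Relative intensity is per scan: a peak's intensity divided by the base peak
of the same scan, so the same m/z at two RTs can be 100 % twice. The primary
peak is the highest XIC point whose most intense in-window spectrum stick
clears the threshold; the observed m/z is that stick's centroid (no
re-centroiding).

Isomer peaks are sought at the same m/z within ±1.75 min of the primary
(fixed; isomers elute near one another), up to the number of database
entries sharing the theoretical mass (equality within 0.001 Da). The peak
rule: a point qualifies when it is a strict local maximum of the XIC (slope
in > 0, slope out < 0) **and** at least 3 of the up-to-4 slopes on each side
agree in sign. Requiring the local maximum is deliberate: a bare 3-of-4 vote
would also mark the shoulders flanking a clean apex; the 4-slope windows
exist to tolerate one noisy slope further out, not to widen the apex. At
chromatogram edges the windows truncate, and every available slope (minimum
2) must agree. Zero slopes count as neither positive nor negative.
Accepted peaks are ranked by intensity, capped at the isomer count, then
renumbered 1..k by ascending RT — matching how identifications are reported
even though the most intense peak is found first.

RT restriction precedence: database RT ± interval wins over LC windows
(the interval is the batch-processing mechanism), which win over the full
run. LC windows are elution regions where fluorescence ≥ 1 % of the trace
maximum, split at local minima, shifted onto the MS time base by the offset
between the two base-peak apexes. Isomer detection always uses the
unrestricted chromatogram around the primary peak, since the ±1.75 min
isomer span exceeds any restriction window.

## MS2 confirmation

Defaults: 100 ppm tolerance, 3 % label threshold, fragment charge {1}
(singly charged fragment ions dominate CID/HCD glycan spectra; charge 2 can
be enabled for large precursors). The precursor scan is the first MS2 scan
at RT ≥ hit RT − 0.1 min whose precursor m/z matches the *theoretical* m/z
within tolerance and whose precursor charge equals the hit charge; scans
lacking a recorded precursor charge match with a warning, since some
converters omit it.

Each above-threshold stick receives at most two annotations. Ranking among
candidate matches is: plain ions before adducts, then smaller |ppm|, then
fewer cuts (simpler fragments are likelier), then fragment id for
determinism. Distinct-peak counting for the Details table merges sticks
closer than one tolerance window before counting, approximating "distinct
peaks" on centroided data.

## MALDI matching

Da-scale tolerance by default (TOF mass error grows with m/z), sodiated
ions by default (permethylated glycans in DHB matrix dominantly sodiate in
positive mode); [M+H]+ is selectable. Every above-threshold peak within
tolerance of a database mass is a hit, so engineered or accidental same-mass
database pairs produce double assignments — reported, not suppressed,
because resolving them is the analyst's call.

`permethylated_mass` is a database-building convenience: free mass +
14.01565 Da per methylation site, with per-code site counts supplied by the
user. The shipped defaults (Hex-class 3, HexNAc-class 3, Fuc/Xyl 2, Neu5Ac
5, Neu5Gc 6) are composition-level approximations — true counts depend on
linkage positions and branching, which a composition cannot see — so real
databases should supply tabled permethylated masses or their own counts.

## The run simulator

The generator emulates: Gaussian elution profiles on a 0.02-min MS1 scan
grid; single sticks at the labeled m/z per charge with a per-mass-class
calibration-style ppm error (default within ±3 ppm, matching low-ppm
Orbitrap errors); isomer mass classes sharing one chromatogram with apex
intensities spanning ~7.6·10⁶ down to ~3.6·10⁵ counts at RTs 13.39 / 13.78 /
14.08 min; MS2 scans 0.05 min after each apex containing the qualifying
fragments at 10–100 % relative intensity plus sub-threshold uniform noise;
a fluorescence trace with matching bumps and an optional LC/MS time offset;
and MALDI peak lists whose mass error is a systematic ±jitter displacement
(calibration error), not a scatter toward zero.

Noise sticks are drawn uniformly over the 500–2000 m/z range but kept at
least 100 ppm away from every searched window (database and decoy masses at
all charges). This is intentional: the fixtures exercise threshold and
tolerance logic deterministically, and false-positive behaviour is probed
with explicit decoy masses (≥ 50 ppm from every planted mass) rather than
with noise lotteries.

What the simulator does **not** emulate — isotope envelopes, chromatographic
tailing, detector saturation, co-eluting interferences, spray instability —
bounds what passing tests show: they validate the search logic and its
parameter semantics, not robustness to real instrument artifacts. Results on
real runs depend additionally on centroiding quality and calibration.
Reported performance numbers from any particular instrument dataset are
dataset-dependent and are not reproduced here; the planted-run statistics
(recovery, decoy rejection, threshold/tolerance monotonicity) are the
desk-reproducible counterparts.

## Numerical choices

* Fragment-mass uniqueness comparisons round to 4 decimals (≈ 0.1 mDa,
  far below any tolerance in use).
* Same-mass grouping of database entries uses 0.001 Da.
* Relative intensities are clamped to ≤ 100 % against floating-point drift.
* Ties in XIC intensity resolve to the earlier scan (stable sort).
* mzXML is written with 64-bit network-order uncompressed peaks so
  write→read round trips are bit-exact; reading accepts 32/64-bit and
  zlib-compressed payloads via pyteomics.

## Known limitations

* No deisotoping or peak-shape fitting: a chimeric stick inside the window
  is taken at face value.
* B-ion masses are bare residue sums (the protonated-species convention of
  the matching step); oxocarbenium-specific corrections are not modeled
  separately from the adduct mechanism.
* The structure-code grammar requires registered 3-letter codes and does not
  validate glycobiological plausibility (any tree is accepted).
* MALDI matching assumes one ion form per search; mixed Na/K populations
  need two passes.
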