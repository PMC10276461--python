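# glyscreen

Accurate-mass identification of fluorescently labeled released N-glycans
from LC–MS/MS runs, with combinatorial fragment enumeration, MS2 spectrum
annotation, and MALDI–TOF peak-list matching for permethylated glycans.

It is written for analytical scientists characterizing the glycosylation
profile of therapeutic proteins: N-glycans are enzymatically released
(PNGase F), labeled at the reducing end by reductive amination with a
fluorescent tag (2-AB or procainamide), separated by HILIC, and measured by
electrospray MS/MS — or permethylated and measured by MALDI–TOF. glyscreen
automates the screening, confirmation and reporting steps that are otherwise
done by hand in a spectrum browser.

## What it computes

**Mass model.** A labeled glycan's neutral monoisotopic mass is

```
M = Σ_c  n_c · m_res(c)  +  m_tag
```

where `m_res(c)` is the residue (in-chain) mass of monosaccharide class `c`
(full sugar minus water) and `m_tag` is the tabled tag mass (2-AB 138.0793 Da,
procainamide 237.1841 Da), which absorbs the terminal water plus the +2H of
reductive amination. Observed ions are `[M + zH]^z+` with
`m/z = (M + z·1.007276)/z`, and mass accuracy is scored in ppm:
`(M_obs − M_theo)/M_theo × 10^6`.

**MS1 screen.** For each database glycan and charge `z = 1..z_max`, an
extracted ion chromatogram is built in a ppm-wide m/z window around the
theoretical m/z; the highest-intensity point passing the intensity threshold
(default: ≥ 25 % of that scan's base peak) is the primary identification, and
a slope-sign rule over the XIC finds chromatographically separated isomer
peaks within ±1.75 min (as many as there are database glycans sharing that
mass). Optional per-glycan expected RTs or an aligned LC fluorescence trace
restrict the searched time range.

**Fragment engine.** A glycan is a rooted tree (root = reducing end with the
tag). Cutting 1–7 glycosidic bonds and collecting the connected pieces
yields every B-ion (one cut, no tag), Y-ion (contains the tag) and internal
ion (≥ 2 cuts, no tag), deduplicated by retained node set. Y-ion masses add
the tag; B/internal ions are bare residue sums, so every single-cut B/Y pair
sums to the parent mass.

**MS2 confirmation.** The first MS2 scan at RT ≥ (hit RT − 0.1 min) with a
matching precursor is annotated: each stick above the 3 % relative threshold
is matched against all fragment ions (plain and +Na / +K / −OH adducts)
within 100 ppm, at most two annotations per peak. The Details statistics
report the percentage of *qualifying* fragments identified (≥ 2 residues,
mass unique within the parent's own set) and any matched masses unique to
the parent versus its same-mass isomers.

**MALDI–TOF matching.** Permethylated-glycan databases are matched as
`[M+Na]+` (or `[M+H]+`) against a single peak list with Da-scale tolerance;
one peak may be assigned to several same-mass glycans.

## Worked example

```python
from glyscreen import labeled_neutral_mass, mz_from_mass
from glyscreen.fragments import enumerate_fragments, parse_structure_code
from glyscreen.simulate import study_plants, make_run
from glyscreen.ms1 import run_ms1, MS1Params

mass = labeled_neutral_mass({"HeN": 4, "Hex": 4, "Fuc": 1}, "ProCA")
print(f"labeled mass : {mass:.4f} Da")     # 1843.7708 Da
print(f"m/z at z=2   : {mz_from_mass(mass, 2):.4f}")  # 922.8927

t = parse_structure_code(
    "GlN(Fuc)GlN Man(Man[a1,3] GlN Gal)(Man[a1,6] GlN)", "A1G1F(a1,3)")
print(len(enumerate_fragments(t)))          # 62 B/Y/internal fragments

plants, db, decoys = study_plants()
scans, lc, truth = make_run(1, plants, decoy_masses=[d.mass for d in decoys])
hits = run_ms1(scans, db + decoys, MS1Params())
```

The MS1 output rows for one glycan of the simulated run (a
monogalactosylated core-fucosylated biantennary glycan whose mass class
elutes as three isomer peaks):

```
       Name  Isomer peak no  RT (min)  Charge (z)  Observed m/z  Theoretical mass (Da)  Observed mass (Da)  Mass error (ppm)  Intensity (count)  Relative intensity (%)
A1G1F(a1,3)               1     13.40           2      922.8927              1843.7708           1843.7709               0.1          7485312.0                   100.0
A1G1F(a1,3)               2     13.78           2      922.8927              1843.7708           1843.7709               0.1          1610001.0                   100.0
A1G1F(a1,3)               3     14.08           2      922.8927              1843.7708           1843.7709               0.1           360006.0                   100.0
```

Isomer peaks are numbered 1..k by ascending retention time; relative
intensity is per MS1 scan, so two peaks at different RTs can both be 100 %.
The same pipeline is scriptable from a shell:

```
glyscreen simulate --seed 5 --out sim/
glyscreen ms1   --run sim/run.mzXML --db sim/db.csv --out ms1_hits.csv
glyscreen ms2   --run sim/run.mzXML --ms1 ms1_hits.csv --fragdb sim/fragdb.csv --out ms2/
glyscreen maldi --peaks sim/maldi.csv --db sim/db.csv --tol 1Da --out maldi_hits.csv
```

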