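# Methods

## The inference problem

A prokaryotic proteome carries at most a few distinct N-glycans, attached
to Asn within the sequon N-X-S/T (X ≠ P). When the glycan is chemically
novel, database-driven glycopeptide identification is impossible; instead,
the glycan's mass is *discovered* as a recurring discrepancy between
observed precursor masses and theoretical peptide masses. This package
implements that discovery chain — open search, delta-mass histogram,
focused re-search, validation, site mapping, quantification and
composition inference — and a ground-truthed simulator to exercise it.

## Search model

**Peptide index.** Proteins are digested with the combined trypsin/LysC
rule (cleave C-terminal to K/R; cleavage before Pro suppressed by default),
up to 3 missed cleavages, semi-specific N-ragged: the C-terminus must be
enzymatic (or the protein C-terminus), the N-terminus may be ragged (every
suffix of a fully specific peptide is indexed). Length bounds 5–50.
Carbamidomethyl-Cys is fixed; Met oxidation and protein N-terminal
acetylation are variable (≤2 per peptide). Reversed-sequence decoys
(`rev_` accessions) are indexed alongside targets. Residue and atomic
monoisotopic masses are fixed constants in code (5 dp residue table;
proton 1.00727646, water 18.01056).

**Candidate generation.** Precursor tolerance is 10 ppm. A spectrum's
candidates are (a) peptides matching the precursor directly and (b), in
open mode, Asn-containing peptides whose mass is 300–2,000 Da below the
precursor; the wildcard delta is the continuous difference, not a grid.
Because the semi-N-ragged index is large (~1.5×10⁵ modified peptide states
on the reference proteome), wildcard candidates are prefiltered with a
fragment-ion index: all naked b/y ladders are pooled into one sorted
array, each spectrum's peaks vote for peptides by binary search, and only
the best-supported candidates (default 8, minimum 2 shared fragments) are
fully scored. Focused mode replaces (b) with exact windows at each given
glycoform mass.

**Scoring.** A hyperscore-style statistic:
ln(1 + Σ matched intensity) + ln(N_b!) + ln(N_y!) + ln(N_cz!), with b/y
matched at 10 ppm (HCD) and c/z at 20 ppm (EThcD). The glycan is treated
as labile in HCD (naked b/y ladder) and retained in EThcD (c/z ladder
shifted by the delta from the site onward). One PSM per spectrum (rank 1);
ties break by matched-ion count, then lexicographic peptide, keeping
results deterministic.

**Site localization.** For a delta-carrying PSM, every Asn position is
tried as the attachment site; the site is assigned only when a unique
position maximizes the matched c/z count *and* at least one matched ion
actually carries the delta (an ion bracketing the site). Otherwise the PSM
is retained unlocalized. This is a deliberate simplification of
fragment-pair bracketing: with complete c/z ladders it is equivalent, and
with sparse ladders it errs toward "unlocalized" rather than a wrong site.

**FDR.** PSMs are ranked by score; the running FDR is cumulative
decoys/targets and the q-value is the cumulative minimum from the bottom.
Confident PSMs require q ≤ 0.01 and ≥4 matched ions. This one-dimensional
PSM-level procedure, plus best-peptide protein grouping, stands in for
proprietary multi-level scoring; the intent (confident identifications at
1% FDR) is preserved with fully open components.

## Histogram analysis

Confident wildcard deltas are binned left-closed in 0.1 Da increments over
[300, 2000). A bin is called predominant when it holds at least
max(5, 3 × expected uniform background count) deltas; adjacent qualifying
bins whose medians differ by less than one bin width merge into a single
call (a mass straddling a bin edge). The refined mass is the *median* of
member deltas, reported to 2 dp — the median is robust to the few deltas
dragged off by precursor-error tails, and for any plausible error model
median and bin-center agree to well under one bin width.

## Validation criteria

Each called mass is judged on its focused-search PSM population, each
criterion passing when ≥80% of the evidence agrees, with ≥5 supporting
PSMs required overall:

- **Oxonium:** the supporting spectrum contains a peak within 20 ppm of a
  registered oxonium m/z (HexNAc 204.087; its secondary fragment 138.0545,
  stored as a literature constant).
- **Sequon:** the localized site lies on an N-X-S/T sequon of the parent
  protein; unlocalized PSMs abstain rather than vote against.
- **Cleavage:** the peptide C-terminus is enzymatic — only the C-terminus
  is judged, consistent with semi-N-ragged searching.

The verdict is the conjunction. The 80%/5 thresholds make an inherently
qualitative judgment explicit and configurable; they tolerate a minority
of mis-localized or noisy PSMs without flipping a verdict, so adding
conforming evidence can never turn a bona fide call into a false positive.

## Quantification and site mapping

Per-residue coverage counts every PSM whose peptide spans the residue.
A sequon is *confirmed* by ≥1 localized glycoPSM, *unconfirmed* when
covered but never modified, *not assessed* when never covered — the three
statuses partition the sequon set. NSAF is SpC/L normalized to sum to 1
per condition (a report-scale multiplier is available but defaults to 1,
since published NSAF tables print on unstated scales). Glycosylation
frequency is protein length divided by confirmed sites, undefined at zero
sites.

## Composition inference

The enumerator walks the full constraint box (defaults C_5–14 H_4–28
N_0–5 O_2–12 S_0–1), solving the H count arithmetically from the mass
residual, and filters by C/H ∈ [0, 4], C/(N+O) ∈ [0.4, 1.25] and
RDB = C − H/2 + N/2 + 1 ∈ [1, 6], with a ±0.005 Da window (ppm mode
available). Results sort by |error|, then atom count, then formula. The
C/H bound is read as carbon over hydrogen (a config flag flips it to H/C;
the reference composition C11H17N3O6 passes either reading, so the choice
is not load-bearing). A zero denominator with non-zero numerator fails the
ratio bound. The ±0.005 Da default matches a query printed to 2 dp whose
true mass sits ~2 mDa away.

Glycan blocks ship as a JSON registry of residue (dehydrated) formulas:
Hex(NAc)2 = C10H16N2O5 (244.1059 Da), HexA(NAc)2 = C10H14N2O6
(258.0852 Da), Hex(NAc)2(CONH2) = C11H17N3O6 (287.1117 Da) — the
carboxamide block is the plain block plus exactly {C+1, H+1, N+1, O+1},
i.e. a CH2NO group replacing one hydrogen at the attachment point. The
reference hexasaccharide Hex(NAc)2–HexA(NAc)2–[Hex(NAc)2(CONH2)]₄ sums to
1650.64 Da (2 dp); glycoform mass is additive and order-independent.

## Synthetic data: what it emulates, what it does not

The generator builds proteins from random tryptic segments (8–21 residues,
internal residues free of K/R, never starting with Pro), which guarantees
every planted sequon sits inside a clean fully tryptic peptide within the
search length bounds. Accidental N-X-S/T motifs are scrubbed, so the
sequon plan is honored exactly and the remaining off-sequon asparagines
serve as carriers for the false modification.

Reference conditions (the `SimConfig` defaults): one 1,199-residue
S-layer-like protein with 6 sequons, 5 glycosylated by the 1,650.64 Da
hexasaccharide (the unoccupied one near the C-terminus); 20 background
proteins of 200–400 residues; 2,000 spectra at fractions 15% glycopeptide
/ 5% false-modification (631.26 Da, off-sequon Asn, no oxonium ions) /
20% plain S-layer / 60% plain background; charges 2+/3+ equiprobable.
Fragment completeness 0.85; 30 uniform noise peaks below the 20th
intensity percentile of signal; log-normal intensities (σ = 0.5 log₁₀
units, oxonium ×2); Gaussian mass error, 3 ppm precursor / 5 ppm fragment
— comfortably inside the 10/20 ppm search tolerances. Spectra carry naked
b/y ions plus a peptide Y0 peak (glycan loss in HCD) and, for modified
peptides, c/z ions retaining the delta (EThcD behaviour); 1,650-class
spectra add the two oxonium peaks. Each spectrum has exactly one truth
record.

Not emulated: chromatography and retention time, isotope envelopes,
co-isolation chimeras, multiply charged fragments, glycan Y-ion series
beyond Y0, real amino-acid composition biases, and shared peptides between
proteins. Passing tests therefore demonstrate the *inference logic* —
delta recovery, histogram calling, criterion discrimination, localization,
FDR control — under a faithful but idealized signal model, not performance
on instrument data.

## Problem sizes and numerical choices

The reference analyses and the reproduction script use the 2,000-spectrum
default simulation (~10⁵ indexed peptide states); unit and property tests
run reduced scenarios (200–500 spectra, 4 background proteins) chosen to
exercise every code path in seconds. At reduced scale the median-refined
predominant mass is reproducible to ~0.01 Da (√n scaling of the median of
~50 deltas with 3 ppm precursor error); at reference scale it is stable at
2 dp across seeds.

Reported rounding follows field convention: delta masses 2 dp, m/z 3 dp,
theoretical compositions 4 dp. All randomness flows from a single integer
seed through `numpy.random.default_rng`; identical seeds give
byte-identical FASTA/MGF output. Degenerate inputs are contracts, not
crashes: an empty glycoform has mass 0, an empty constraint box returns an
empty candidate list, a spectrum matching nothing scores 0, a protein with
no PSMs maps all sequons "not assessed", and zero confirmed sites leaves
the glycosylation frequency undefined rather than infinite.

## Known limitations

- The wildcard delta must sit on Asn; O-glycans and non-Asn chemistries
  are out of scope by design.
- Validation operates per modification mass over its PSM population;
  a mass carried by both a true glycan and a co-incident artifact would
  receive a single blended verdict.
- The score is uncalibrated (no p-values); confidence comes entirely from
  the target–decoy procedure, so very small datasets yield coarse
  q-values.
- Composition enumeration covers C/H/N/O/S only — phospho- or
  metal-bearing sugars would need an extended element table.
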