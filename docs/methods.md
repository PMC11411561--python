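# Methods

## Plume-mixing energetics

The model treats a hydrothermal plume as a two-endmember conservative
mixture: a reduced vent fluid (H₂, H₂S, CH₄, CO at their endmember
concentrations) diluted *d*-fold into oxygenated deep seawater.  For each
vent-derived species, `c_mix = c_sw + (c_em − c_sw)/d` with the deep-sea
background of the vent gases taken as zero; the oxidant, sulfate, pH and
ionic-strength terms keep their seawater values, since at the dilutions of
interest (d ≥ 10⁴) the fluid contribution to them is negligible.  Above
d = 10³ the mixture is taken as thermally equilibrated with ambient
seawater; below that an endmember temperature, when supplied, mixes
conservatively.

In-situ reaction energies are `ΔrG = ΔG°(T) + R·T·ln Q`, per mole of the
electron donor.  Standard-state data are CODATA/SUPCRT-consistent aqueous
formation properties at 298.15 K (kJ/mol): H₂O(l) −237.14/−285.83 (ΔGf/ΔHf),
H₂(aq) +17.7/−4.2, O₂(aq) +16.5/−11.7, H₂S(aq) −27.92/−38.6, SO₄²⁻
−744.46/−909.6, with H⁺ at zero.  Temperature correction is Gibbs–Helmholtz
at constant reaction enthalpy, `ΔG°(T) = ΔH° − (T/298.15)(ΔH° − ΔG°)`;
the pressure correction is neglected.  Activities are `γ·m` with γ = 1 for
neutral dissolved gases, γ(SO₄²⁻) = 0.12 at seawater ionic strength,
a(H₂O) = 1 and a(H⁺) = 10^(−pH).

Default seawater background (all overridable via the YAML config):
O₂ = 250 µmol/kg, SO₄²⁻ = 28 mmol/kg, pH 8.0, T = 275.9 K (2.7 °C, the
potential temperature of the non-buoyant plume layer), P = 265 bar.

Design notes:

- **Decade structure.** Only the donor activity changes with dilution, so
  `ΔrG(10·d) − ΔrG(d) = R·T·ln 10` exactly (≈ 5.28 kJ at 275.9 K).  The
  temperature default is corroborated by this spacing in the reference
  energetics table the test suite checks against.
- **Units.** The reference table labels its values kJ L⁻¹, but they behave
  as kJ per mole of donor (decade spacing equals R·T·ln 10; per-electron
  rows are per-mole rows divided by n_e).  The module computes per-mole
  values as primary and reports `ΔrG × c_em(donor)` (fluid density 1 kg/L)
  as the separate litre-basis quantity — alongside, never in place of, the
  per-mole value.
- **Absolute calibration.** The exact thermodynamic database, oxidant
  value and pressure treatment behind the reference values are not
  published; with the defaults above the computed 10⁶-dilution yields sit
  within 0.3% of the reference (tolerance ±3% to absorb database
  dependence).  CO oxidation energetics are deliberately not computed:
  micromolar endmember CO dilutes to picomolar in the plume.
- **Rounding** for report output is half-away-from-zero to two decimals,
  matching the printed precision of the reference table (plain `round`
  would banker's-round −111.335 to −111.33 instead of −111.34).

## CTD plume classification

The printed field thresholds are strict inequalities that overlap
(background < 0.01 ΔNTU, above/below plume < 0.02, non-buoyant plume
> 0.02, rising plume > 0.06).  The classifier uses the disjoint
convention background [0, 0.01), near-plume [0.01, 0.02), non-buoyant
[0.02, 0.06], rising (0.06, ∞), which honours every strict inequality,
makes the classifier total and monotone, and fixes the boundary
0.06 → non-buoyant.

Near-plume bottles are resolved into above/below by vertical context.
"Above" and "below" refer to position relative to the plume layer, so the
reference depth is the **deepest bottle with plume-range turbidity**
(> 0.02 ΔNTU) in the cast — the bottom of the detected plume — rather than
the depth of the turbidity maximum: in a vertical cast through a rising
stem the turbidity maximum can sit well above the spreading layer, which
would invert the labels.  When a cast has no plume-range bottle the
turbidity-maximum depth is the fallback; ties go to above; a cast whose
only turbidity-bearing bottle is near-plume has no vertical reference and
stays unclassified.  Eh is accepted as an optional corroborating field but
never overrides turbidity (no Eh values are available in the shipped
table).

The shipped 20-bottle reference table is audited by checking each printed
label against its own one-sided threshold, tolerating equality at the
printed resolution (0.01 ΔNTU printed for a background bottle is
compatible with "< 0.01" after rounding).  Three printed labels violate
their thresholds — a background bottle at 0.011, a below-plume bottle at
0.021, and a plume bottle at 0.016 — and are reported as discordance
warnings, not forced to match; the field classification presumably drew
on the Eh profile, which is not printed.

## Marker-gene normalization

Genome equivalents (GE) are the arithmetic mean depth of 16 universal
single-copy ribosomal genes; since each genome contributes one copy of
each marker, GE estimates the summed genome coverage of the community.
Carriage is `100 × depth(gene)/GE`, a coverage-weighted percent of
genomes; values above 100% are flagged as multi-copy, never clipped.
Gene depths are summed over gene variants before dividing by GE (the
alternative — averaging per-variant fractions — double-counts genomes
carrying several variants).  The identity of the 16 markers is
configuration: the module operates on whichever 16 depth values the input
supplies.  Raw counts are converted to depth as
`count × read_length / gene_length`, read length defaulting to 250 nt
(2×250 bp libraries).

## Expression metrics

`RPKM = reads × 10⁹ / (length × total_mapped_reads)` with a library-wide
total that may exceed the per-feature sum; `TPM = 10⁶ × (reads/length) /
Σ(reads/length)`, summing to 10⁶ per sample.  TPM denominators are
computed over the whole supplied table (per-library); restricting the
table to one MAG gives the per-MAG variant.  Fragments (read pairs) are
the count unit; both metrics are homogeneous of degree zero in that
choice.  The housekeeping baseline is the arithmetic mean TPM of a
configured reference-gene set; ratios with a zero denominator are
reported as missing, never as infinities.

## CODH form classification

Cox-annotated genes on one contig and strand with intergenic gaps
≤ 500 bp (a standard prokaryotic operon heuristic, configurable) form a
candidate operon when at least two structural subunits (coxS/M/L) are
present; gene order follows transcription direction.  Decision order:
(1) missing any of S/M/L → `partial` — structure is checked before the
motif because a truncated operon cannot be form-typed reliably from the
loop alone; (2) coxL carries AYRGAGR → `form_II`; (3) coxL matches
AYxCSFR (one wildcard, the canonical form I loop) → `putative_form_I`;
(4) otherwise `unknown`.  Accessory genes coxD/E/F/G are searched
genome-wide — form II operons keep no consensus accessory arrangement —
and reported as evidence only.  Classification is deterministic,
independent of input gene order, and invariant under mirroring a contig
(coordinates flipped, strands swapped, translations unchanged).

## Synthetic data

Each generator draws from its own PRNG stream derived from the master
seed (`default_rng([seed, stream])`), so generators are pure functions of
their config and adding one never perturbs another.  Ground truth is
emitted with every dataset and round-trips through JSON.

- **CTD casts**: 21 bottles at 60 m spacing, a Gaussian anomaly (peak
  0.5 ΔNTU, σ = 80 m, centred at 2600 m — matching the observed rising
  plume magnitude and depth) over |Normal(0.005, 0.002)| background.
  True categories come from the noise-free signal via the thresholds.
- **Mock communities**: 500 genomes with log-normal coverage
  (µ = ln 3, σ = 0.5) and taxon labels; each gene family is planted into
  exactly `round(f·n)` genomes — mock composition is known by design, the
  way staggered mock communities are built — with default carriage
  fractions set to the observed plume values (coxS 0.51, hydrogenase
  0.38, soxY 0.25).  Markers see the summed coverage exactly; optional
  Poisson depth noise with a configurable quantum.  Noise-free recovery
  equals the coverage-weighted ground-truth fraction exactly; against the
  planted count fraction it carries only coverage-weighting noise
  (≈ 1.2% SD per seed at the defaults), so the across-seed mean recovers
  the planted fraction well within ±2 points.
- **Operon fixtures**: per seed, five instances of each class (form II
  S-L-M with AYRGAGR, form I S-L-M with AYxCSFR, partial L-S, motif-less
  S-L-M), each with a strand-flipped duplicate, plus singleton contigs
  with genes beyond the gap threshold and accessory genes planted far
  outside the form II operons.  Background proteins are rejection-sampled
  to contain neither motif, so generative labels are exact oracles.
- **Transcriptomes**: 50 features, lengths uniform on [300, 3000] nt,
  log-normal(0, 1) expression rates, multinomial counts over
  length-weighted rates at a 10⁶-read library; a noise-free mode emits
  expected counts, on which TPM is exactly proportional to the rates.

What the generators do **not** emulate: read-level sequencing error,
assembly and binning artefacts, taxonomic misannotation, compositional
correlations between gene families, and inter-cast oceanographic
structure.  Passing recovery tests therefore demonstrates correctness of
the normalization and classification arithmetic, not robustness to
upstream annotation error.

## Problem sizes

Defaults throughout (500-genome communities, 10-seed recovery, 5-seed ×
40-operon classifier checks, 10⁶-read libraries) were chosen as the
smallest sizes at which the sampling-error bounds above are comfortably
resolved; all are plain config parameters.

## Known limitations

- No geochemical speciation or ion-interaction (Pitzer/Debye–Hückel)
  model; activity coefficients are fixed constants.
- Absolute ΔrG inherits thermodynamic-database and pressure-treatment
  uncertainty of order a few percent; dilution *trends* are exact.
- The vertical-context rule is a reconstruction; the original
  above/below calls also used unpublished Eh profiles.
- Carriage percentages are coverage-weighted, not genome-count-weighted;
  the two differ in communities with strong coverage heterogeneity.
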