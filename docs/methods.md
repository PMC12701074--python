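# Methods

## The fragment-mass model

A heterobifunctional K-C cross-linker carries an NHS ester (couples to the
lysine Nζ amine, losing one H) and a haloacetamide (alkylates the cysteine
Sγ thiol, losing one H). What remains between Nζ and Sγ is the *bridge*
composition, shipped as configuration data: SIA C2H2O (spacer 4.2 Å), SBAP
C5H7NO2 (9.0 Å), SIAB C9H7NO2 (10.6 Å). Users can register further linkers
from a TOML/JSON file without code changes.

Oxidation adds one oxygen on the cross-linked sulfur, so the oxidized
cross-link adds `bridge + O − 2H` to the sum of the two peptide neutral
masses. Collisional activation cleaves the C-S bond adjacent to the
sulfoxide with hydrogen rearrangement:

* the cysteine-side peptide keeps nothing of the linker and loses H2S from
  its own side chain (alkene/dehydroalanine remnant, −33.987721 Da — the
  same for every K-C linker, because the sulfur leaves with the other
  fragment);
* the lysine-side peptide carries the balance as a sulfenic-acid remnant
  (`intact addition + 33.987721`), which may dehydrate to the
  unsaturated-thiol remnant (−H2O).

Mass conservation `M(α_S) + M(β_A) = M(precursor)` holds exactly by
construction and is the central constraint of the search. All masses are
monoisotopic (high-resolution Orbitrap data); charge arithmetic uses the
proton mass 1.007276 Da. Oxidized carbamidomethyl cysteine loses RSOH
(R = carbamidomethyl; C2H5NO2S, 107.004 Da), a diagnostic of the cleavable
site. Pre-oxidation (non-cleavable) cross-link masses (`bridge − 2H`) and
dead-end species (hydrolyzed NHS side `bridge + O`; cysteine-quenched side
`bridge − 2H + Cys`) are provided as derived constants.

Chemistry comparisons use relative ppm tolerances throughout (default
10 ppm); published observed values for the worked-example peptides deviate
from theory by up to ~5 ppm.

N-terminal α-amines are not treated as NHS-reactive sites by default — the
cross-linkable residue set is lysine only (the simple, conservative choice);
an index built with a different digestion can opt in by populating
additional sites.

## Digestion and the peptide index

Trypsin cleaves after K/R but not before P. A cross-linked lysine is not
cleaved, so a linkable K must be internal to its peptide (or sit at the
protein C-terminus) and implicitly consumes a missed cleavage. Defaults: ≤2
missed cleavages, peptide length 5–50. Non-cross-linked cysteines carry
fixed carbamidomethyl. Variable oxidation states (oxidized CAM cysteine,
Met/Trp oxidation) are not enumerated as search-space modifications; the
RSOH loss is available as corroborating evidence only. Decoys reverse the
full protein sequence keeping the C-terminal residue and are re-digested;
decoy peptides colliding with a target sequence are flagged shared and
excluded from decoy accounting.

## Identification

**MSn mode.** (1) MS2 signature-pair detection: every peak pair, over
fragment charge hypotheses 1..z−1 whose charges sum to ≤ z, whose neutral
masses sum to the precursor neutral within the MS2 tolerance (default
20 ppm). A peak at `α_S − H2O` (within 0.02 Da) corroborates the α/β
orientation; α_T is never required — for SIAB in particular the
sulfenic-acid fragment resists dehydration. (2) MS3 matching: candidate
peptides whose mass plus remnant equals the MS3 precursor neutral within
10 ppm, with the remnant localized on a linkable K (α remnants) or a C
(β_A); b/y ions are matched at 0.6 Da (ion-trap MS3) and scored with a
binomial tail score: with `k` of `n` theoretical ions matched and a
per-ion random-match probability `p` estimated from spectrum peak density,
score = −log10 P(X ≥ k), X ~ B(n, p). Counts, not intensities, drive the
score, which keeps it deterministic and calibration-friendly. (3)
Integration: a cross-link spectrum match (CSM) requires a signature pair,
MS3 identifications matching the pair's α (α_S or α_T) and β masses, and
the α+β+intact sum matching the MS1 precursor within 10 ppm. Evidence from
only one side is emitted flagged `single_sided` and excluded from default
FDR reporting — accepting it would leave the second peptide unverified.

**Stepped-HCD MS2 mode.** Candidate α(K)/β(C) pairs are enumerated from the
mass-sorted index so that `m(α)+m(β)+intact` matches the precursor within
tolerance; a detected signature doublet constrains the α-side mass (two
half-windows around the doublet-implied masses). Each side is scored on its
remnant-modified sequence ions in the same spectrum at 20 ppm; the combined
score is the sum.

Ties are broken deterministically: higher score, then smaller absolute
precursor ppm error, then lexicographic peptide sequence.

**FDR.** CSMs are classed TT/TD/DD by the decoy status of the two sides.
Scanning thresholds in descending score, FDR(t) = max(0, TD−DD)/TT, capped
at 1; q-values are the running minimum. Filtering at a level keeps
two-sided CSMs with q below it (TT only by default). CSM-level FDR is the
default reporting level; linkage-level grouping (best CSM per residue pair)
is available downstream of `collapse_to_unique_linkages`.

**Aggregation.** CSMs collapse to unique linkages keyed by (protein A, K
residue, protein B, C residue) in 1-based protein coordinates, verified
against the protein sequences (a mismatch indicates index corruption and is
an error, not a warning). Peptides shared across proteins mark the linkage
ambiguous with all candidates listed; the lexicographically first location
is canonical. The reproducibility filter keeps linkages observed in ≥2
biological replicates with the same linker (at least one linker).

## Structure mapping

Residue mapping (protein numbering → structure chain/numbering offsets) is
supplied as a table so the core runs offline; chains whose residue identity
disagrees with the expected amino acid are excluded with a warning, never
silently used. For each linkage the Cα–Cα distance is computed in every
covering model/chain combination; intra-protein linkages also measure every
inter-chain combination in homo-oligomeric models, and the minimal distance
with its provenance is recorded. A linkage is satisfied strictly below the
threshold (default 30 Å). Homomer rescue — satisfaction achieved only
through an inter-chain distance while all same-chain distances violate — is
accounted separately and can only increase the satisfied count. Residues
without a Cα atom are unmapped in that model (no imputation).

Predicted models carry per-residue pLDDT (B-factor column) and a PAE
matrix (standard `predicted_aligned_error` JSON). The PAE of a residue pair
is the mean of the two directed entries (the matrix is nearly symmetric in
practice and the mean is the symmetrization that treats both directions
evenly); confidence gating keeps pairs with PAE strictly below 20 by
default. The pLDDT of a pair is the minimum of the two residues, cutoff 70
(the conventional "confident" boundary) — both configurable.

Secondary structure labels are consumed from standard assignment output
(DSSP letters), grouped {H,G,I}→helix, {E,B}→sheet, everything else→loop.
Enrichment for cross-linked K and C counts classes over satisfied records
only (distance < 30 Å) and divides by the background class frequency of
that residue type over the model set, making the profile invariant under
duplication of the background. A Cα-only fallback assigner (i→i+3 distance:
<6.5 Å helix, >9.0 Å extended) exists for geometric fixtures; real analyses
should supply DSSP output.

## Network assembly

Inter-protein linkages become edges between unordered protein pairs; every
cross-linked protein is a node, so intra-only proteins appear without
edges. Ambiguous linkages are excluded from edge building by default.
Intra-protein (potential homodimer) evidence is reported separately, never
as self-edges. Reference edge sets and complex definitions are local file
exports; identifier reconciliation is an explicit user-supplied mapping —
no fuzzy matching, no live API calls. Complex coverage uses a strict >50%
rule for the "over half recovered" statistic.

## The synthetic-data generator

The generator emulates the acquisition this toolkit targets: precursor
charges supported on 4–8 (weighted toward 4+), MS2 cleavage emitting the
signature fragments at the charge splits of the precursor (both sides
capped at 4+), α_T emission for SIA/SBAP but not SIAB, MS3 sequencing of
the top signature-candidate peaks with the selection budget split between
the α and β sides (mirroring pair-targeted MS3 triggering; default 4
scans), remnant-modified b/y ladders at 1–2+, Gaussian relative mass error,
independent per-peak dropout, and uniform-m/z noise with exponential
intensities (signal intensities log-normal — arbitrary but fixed, since the
scorer uses counts). Planted links are drawn from the digested peptide
space, so every planted link is realizable by construction, and all
generators are byte-deterministic under the seed.

What it does **not** emulate: chromatography and co-isolation, isotope
envelopes, intensity structure of real fragmentation, dynamic exclusion,
shared/ambiguous planted peptides, or post-translational modification
heterogeneity. Passing the closed-loop tests therefore demonstrates the
correctness of the search logic and mass model and the internal consistency
of the FDR accounting — not performance on real LC-MSn data, where scoring
robustness and chimeric spectra dominate difficulty.

Problem sizes used by the test suite and acceptance script: 50-protein
proteomes with 100 planted links for recovery (noiseless, and 100 noise
peaks/spectrum with 5 ppm error and 0.9 detection probability), and
30-signal-protein runs searched against a 150-protein entrapment database
over three seeds for FDR calibration. These sizes give stable statistics
while keeping the whole suite fast on a single CPU.

## Known limitations

* The scorer is intentionally simple (binomial counts); it has no
  intensity model and no machine-learned rescoring, so absolute score
  scales are not comparable across instruments.
* Variable modifications are not searched; heavily modified real samples
  will lose identifications to the fixed-modification assumption.
* The stepped-HCD mode scores each side on remnant-modified ladders only;
  ions of the intact cross-linked species are not modeled.
* mzML support covers centroided spectra with standard CV terms (32/64-bit
  float arrays, zlib or no compression); vendor rawfiles and profile data
  are out of scope.
* Distance mapping is straight-line Cα–Cα; solvent-accessible surface
  distances and steric checks are not computed.
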