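# Methods

This note documents the models, constants, numerical choices and known
limitations behind `ranapep`. Nothing here states a result the test
suite or `scripts/acceptance.py` does not itself compute.

## Mass model

Peptide neutral monoisotopic mass is the sum of residue masses plus
one water (18.010565 Da), plus −0.98402 Da when the C-terminus is
amidated (-OH → -NH2), plus −2.01565 Da per intramolecular disulfide
bond (loss of two hydrogens). Residue masses are the standard
monoisotopic values (G 57.02146 … W 186.07931); proton mass is
1.0072765 Da and the isotopologue spacing is 1.0033548 Da (C13−C12)
divided by the charge. The placeholder residue `J` carries the shared
Leu/Ile mass (113.08406 Da) so that masses, fragments and spectrum
graphs are computable before isomer assignment.

Positions are 1-based throughout, matching the superscript convention
used for these peptides (e.g. Leu^6). For reporting, masses are
rounded half-up to 3 decimals and ppm errors to 1 decimal. The bundled
28-peptide inventory reproduces all published theoretical masses
within ±0.001 Da under this model. Several published ppm cells are
*not* reproducible from the rounded printed mass pairs (the original
table evidently used unrounded internal masses); the report builder
recomputes ppm from its own theoretical masses and flags such cells
(`ppm_mismatch`) rather than copying them.

## Fragment model

* b ions are the protonated prefix residue sum; a = b − CO
  (27.994915); c = b + NH3 (17.026549).
* y ions are the protonated suffix sum plus water (plus the amide
  delta when the suffix carries the C-terminus); z ions are modelled
  as the radical z• species, y − NH2 (16.018724). The even-electron
  z+1 form can be emitted behind a flag (default off — published
  annotations do not fix which reduced forms were observed).
* Multiply charged fragments use (neutral + z·proton)/z; fragment
  charge is capped by the caller (the simulator uses singly charged
  fragments by default).
* Secondary fragmentation satellites: a y ion whose fragment contains
  Lys additionally loses K (128.09496); a Lys-Lys run additionally
  loses KK. Only y-series satellites are generated — these are the
  losses actually diagnostic in this peptidome.
* w ions: a z• ion whose N-terminal residue is Leu loses the
  isopropyl radical (43.05478 Da); Ile loses ethyl (29.03913 Da); `J`
  yields both candidate w ions tagged with the hypothesis each would
  confirm. The two hypotheses are separated by exactly one CH2
  (14.01565 Da). The Ile methyl loss (d-type, 15.023 Da) is not
  generated: only the two diagnostic radical losses are modelled.
* Internal and immonium ions are out of scope.

**Disulfide visibility.** A single backbone cleavage strictly between
the two Cys of an intact S–S bond cannot separate the fragments, so
such ions are predicted with `visible=False` and excluded from
simulation and coverage. Opening a bond (ETD preferentially cleaves
S–S; the subsequent activation fragments the ring-opened species)
recomputes c/z• ions against the remaining bonds, exposing the former
loop interior — this is what reveals the TKKC stretch inside the
CSITKKC Rana box. Hydrogen bookkeeping at the opened Cys is
configurable (`none` / `plus_H` / `minus_H`, default `none`): the
published spectra do not constrain which species dominates, and with
`none` the opened-loop ions coincide with the linear-peptide values.

## Synthetic spectra

The simulator emits every visible predicted ion of the chosen
activation mode, then applies, in order: Bernoulli peak dropout
(probability `dropout_prob`), multiplicative Gaussian m/z jitter
(sigma `mz_jitter_ppm`), and `noise_peak_count` uniform noise peaks in
[100, precursor m/z] at half the weakest signal intensity. Intensities
are either uniform or 1/rank (`rank_decay`) — real intensity structure
is not knowable from the published material, so nothing downstream
scores on intensity beyond tie-breaking. Spectra are deterministic
given the config seed.

What this emulates: Orbitrap-class centroided peak lists with ppm-
scale mass error, incomplete ladders and modest chemical noise. What
it does not: isotope envelopes, multiply charged fragment
distributions, co-isolation, intensity heteroscedasticity, deamidation
and other artefacts. Passing the simulate-then-recover benchmarks
therefore demonstrates correctness of the inference logic under the
stated noise model, not instrument-grade performance on real data.

MGF I/O is a thin layer over `pyteomics.mgf` (write∘read is the
identity on title, charge, and m/z to 4 decimals); a malformed peak
line is reported with its line number.

## Annotation and Leu/Ile calling

Matching is per-ion nearest-peak within a ppm tolerance — mirroring
manual annotation practice and independent of ion order; a peak may
satisfy several ions, and ties on one ion resolve to smallest |ppm|,
then higher intensity. Default tolerance is 10 ppm (the inventory's
measured errors are ≤ 4.7 ppm); it is a configurable default, not a
claim about the original manual tolerance. A cleavage site counts as
covered when any visible backbone ion cut there matched; coverage is
covered sites / (length − 1).

An isomer call at a `J` position requires (default): the parent z• ion
matched; exactly one of the two hypothesis w ions matched; and the
matching peak not already explained as a backbone or satellite ion of
the candidate (`exclusive_evidence`) — an isobaric coincidence must
not masquerade as a side-chain loss. Zero or two surviving hypotheses
yield `undetermined`; the N-terminal residue has no covering z ion and
is always `undetermined` (the same structural limit that leaves one of
temporin 1Da's six isomers unresolved in practice). Under 30% dropout
the caller abstains rather than errs — verified over seeded runs.

## De novo sequencing

Nodes of the spectrum graph are prefix-mass hypotheses: each peak is
read as a singly or doubly protonated b (or c) fragment, plus a
virtual source (0) and sink (precursor residue-sum mass, which
requires the C-terminus assumption to be stated). Edges are residue-
mass gaps within a ppm tolerance of the larger node mass (floored at
200 Da); Leu/Ile edges are labelled `J`; Lys and Gln remain distinct
edges at ≤10 ppm below ~1.8 kDa. Where no single residue fits a gap
above 100 Da, unordered two-residue compositions are enumerated and
reported as paired alternatives, e.g. `(PS)`; gaps needing ≥3 residues
terminate the tag — longer gaps cannot be read confidently by hand
either.

Tags are source-to-sink paths (best partial paths if none is
complete), scored by supporting peak count with deterministic
tie-breaks (fewer composites, complementary-ion support, charge-
hypothesis parsimony, summed intensity, lexicographic). Complete
candidates are then re-ranked by in-silico verification — the same
confirmation step applied to manually read sequences: predict the
candidate's full fragment complement, count explained spectrum peaks,
penalise predictions with no peak, and use the summed |ppm| of the
matches as the final numeric tie-break. The last criterion is what
separates the true sequence from same-mass rearrangements whose
coincidental matches sit several ppm off. DFS path enumeration is
budgeted (50,000 paths) to bound worst-case graphs.

Candidate verification (`verify_candidate`) reports coverage and
precursor agreement; a precursor differing from the candidate mass
beyond tolerance is reported as a mismatch in Da (e.g. 28.006 Da for
an Arg→Lys substitution) while matching still proceeds. Assembly of
full sequences from proteolytic pieces uses greedy maximal exact
suffix-prefix overlap (default minimum 3), with contained fragments
absorbed; the published fragments are exact substrings of their
parents, so mismatching overlaps are not modelled.

## Family classification

Rules are applied in order, since the families are defined by
partially overlapping features:

1. **BRP** — a ≥5-residue exact substring overlap with the bradykinin
   core RPPGFSPFR or its Thr6 analog RPPGFTPFR (5 is the shortest
   secreted fragment, FSPFR). Running this rule first prevents short
   Cys-free BRP fragments from being read as temporins.
2. **Rana box** — an annotated disulfide whose two Cys enclose 3–5
   residues with the second Cys at (or one short of) the C-terminus:
   brevinin 1 up to 26 residues, brevinin 2 beyond (the observed
   lengths are 17/24 vs 29/33; any cut in 25–28 gives the same
   partition).
3. **Temporin** — 10–14 residues, amidated, Cys-free.
4. **MRP** — 20–26 residues, amidated, Cys-free.

Anything else is `unclassified` — deliberately so for the cDNA-cloned
transcriptome sequences, which carry no terminal or disulfide
annotation.

## Targeted bradykinin-variant search

The variant space is: the core and its single substitutions (default
Ser6→Thr6), each optionally N-extended (DV) and C-extended (I or IA),
then truncated by up to 4 leading and 2 trailing residues (minimum
length 5) — the windows the detected proteolytic fragments actually
span. Deduplicated variants are screened against precursor masses (or
spectra, with singly charged b/y diagnostic-ion confirmation) at a ppm
tolerance; zero tolerance demands exact equality. Against the 28
measured masses at 10 ppm, exactly the 13 BRP entries hit.

## Benchmark sizes and determinism

The standard benchmarks use 100 random peptides (length 8–14, amidated)
for de novo recovery and 50 random peptides (length 8–20, ≥2 Leu/Ile
beyond position 1) per condition for isomer calling — sizes at which
the binomial uncertainty on a 100% rate is already below a percentage
point, while the whole suite stays fast. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

* No intensity model beyond rank decay; no FDR/decoy machinery.
* Charge deconvolution is hypothesis-based (charges 1–2), not
  envelope-based.
* The Leu/Ile caller requires z•/w evidence; residues at position 1
  (and positions whose z ions are suppressed) stay undetermined.
* Family rules are tuned to ranid skin peptidomes; they are not a
  general AMP classifier.
* Novelty flags in reports compare only against locally supplied
  sequence sets; no remote database search is performed.
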