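# Methods

## The assay being modeled

`crabreap` is an in-silico model of a shuttle-vector assay that measures
how O4-alkylthymidine (O4-alkyldT) lesions affect DNA replication in
*E. coli*: the **competitive replication and adduct bypass (CRAB)** readout
for bypass efficiency and the **restriction endonuclease and post-labeling
(REAP)** readout for the mutation spectrum at the lesion site.

A 12-mer ODN carrying one O4-alkyldT (written `X`) is 5'-phosphorylated and
ligated to a 10-mer, and the resulting 22-mer is threaded into an
EcoRI-linearized single-stranded M13 genome between two scaffold-defined
junctions.  The lesion genome is co-transfected with a lesion-free
competitor genome at a known molar ratio; after replication in cells, PCR
across the insert region yields a duplex that is digested sequentially with
two restriction enzymes around a phosphatase (SAP) / kinase (PNK) labeling
step.  The digestion order selects which strand's released 10-mer carries
the radiolabel:

* **BbsI first** (GAAGAC(2/6), a Type IIS cutter) labels the lesion-situated
  strand, releasing d(p\*GGCGMGCTAT), where M is the base inserted opposite
  the lesion during replication;
* **MluCI first** (^AATT) labels the complementary strand, releasing
  d(p\*AATTATAGCN), with N = complement(M).

The competitor genome releases a 13-nt fragment under both schemes and
serves as an internal standard.  Native PAGE resolves 10mer-A and 10mer-G
from 10mer-T on the lesion strand, but 10mer-C co-migrates with 10mer-T;
on the complementary strand N=A and N=G resolve, which is what quantifies
the T→C outcome.  Combining both schemes therefore disambiguates all four
substitution outcomes.  Putative −1/−2 frameshifts would appear as 9-/8-nt
fragments; loss of a recognition site (large deletion) yields no product
fragment and is treated as lack of bypass.

### Bypass efficiency and mutation frequency

For one replicate,

    bypass (%) = (lesion signal / competitor signal)
               / (control signal / competitor signal)
               / (r_lesion / r_control) × 100

where the lesion signal sums *all* 10-mer product bands of the lesion
channel, the control channel is the lesion-free genome processed in
parallel, and `r_lesion`, `r_control` are the genome:competitor molar
mixing ratios (the division convention for the ratio correction is fixed
here: equal mixing ratios leave the formula untouched).  Mutation
frequency is `1 − f_T` of the solved spectrum.

### Spectrum solving

Each scheme contributes linear constraints on the simplex vector
p = (f_T, f_C, f_A, f_G): the lesion-strand scheme observes f_A, f_G and
the merged f_T + f_C; the complementary-strand scheme observes all four via
N.  Per replicate the constraints are stacked (intensities normalized
within each scheme's 10-mer bands) and solved by non-negative least
squares with a heavily weighted normalization row, then renormalized onto
the simplex.  When the two schemes are consistent the solution is exact;
the T/C split is determined only by the complementary-strand rows, so
corruption of the merged T/C band cannot move it.  9-/8-nt band fractions
(averaged over schemes) enter as f_del1/f_del2, scaling the substitution
simplex to 1 − f_del1 − f_del2.  Replicates are aggregated as arithmetic
mean ± sample SD (ddof = 1), with n = 3 replicates as the default design.

## Digestion engine

Coordinates are 0-based, half-open, in the top-strand frame; cuts are
between-base indices.  Enzyme geometry ships as an editable TSV with cut
offsets relative to the recognition start (BbsI 8/12, MluCI 0/4, EcoRI
1/5); bottom-strand sites mirror the geometry (a site at [i, i+L) cuts the
top strand at i+L−bottom_cut).  Sites whose cut positions fall outside the
substrate do not cleave and are skipped.  Label bookkeeping follows the
chemistry: restriction cuts create 5'-phosphates, SAP converts
(labeled-)phosphates to 5'-OH, PNK converts 5'-OH to labeled phosphate,
and PCR-product termini carry a 5'-hexylamino modifier that neither enzyme
touches — which is exactly why labels end up only on 5' ends created by
the *first* digestion.  The end-chemistry vocabulary therefore includes
`amino` alongside OH/phosphate/labeled_phosphate.

Two simplifications: recognition-site/cut-site connectivity is not
re-checked after the first digestion (irrelevant for the assay geometry,
where sites and cuts never interleave), and digestion is complete (no
partial-digest kinetics or star activity).

## Construct model and primer matching

Flank sequences are read off the scaffold reverse complements: scaffold 1
bridges 24 nt of vector to the first 8 nt of the insert, scaffold 2 the
last 5 nt of the insert to 20 nt of vector.  Junction bridging requires
exact complementarity over at least 4 nt of the insert arm; a mismatched
scaffold is an assembly error naming the junction.  Beyond scaffold reach
the vector is represented by a configurable context; the shipped default
downstream context is a lacZα-derived **synthetic fixture** that provides
the reverse-primer site and contains no BbsI/MluCI/EcoRI site — it is not
the true M13mp7(L2) sequence, which the printed oligos do not determine.

PCR is modeled as exact duplex realization of the primer-bounded region.
Primers are matched by their 3'-terminal anchor (15 nt by default, exact
and unique), and the product inherits the full primer sequence at its
ends — real PCR semantics.  This matters because the forward primer's
5'-proximal region differs by one base from the scaffold-derived flank, so
full-length exact matching would be unsatisfiable with the printed
sequences; anchored matching also implements stripping of the 5'-amino
modifier.  Lesion codes never survive into amplicons: replication-outcome
enumeration substitutes M ∈ {T, C, A, G} (or deletes 1–2 nt at the site)
before extraction, and extracting an X-bearing template is an error.

The competitor construct is a declared synthetic fixture: the printed
25-mer alone bridges neither scaffold and contains no BbsI site, so the
default competitor insert (`AGTGGAAGACAT` + `GGCGATAAGCTAT`) keeps the
printed 25-mer's 3'-terminal 15 nt and the same scaffold junctions, and
releases the 13-nt fragments under both schemes.

## Mass and fragment-ion model

Monoisotopic masses are summed from elemental compositions shipped in a
versioned table (`data/mass_constants.tsv`).  Baseline: neutral linear
5'-phosphate/3'-OH molecule = Σ residues + H2O; 5'-OH subtracts HPO3
(79.96633 Da); the hexylamino modifier adds C6H13N; a radiolabeled
phosphate uses the ordinary 31P mass (the label affects visibility, not
mass arithmetic).  An O4-alkyldT residue is dT + CnH2n, so homologous
lesions differ by 14.01565 Da per CH2 and the branched isomers
(nPr/iPr; nBu/iBu/(S)-sBu/(R)-sBu) are isobaric — stereochemistry is
registry metadata only.

CID fragments use the standard DNA w / a−B series (w: 3' fragment with
5'-phosphate; a_k ≡ M − w_{n−k}; a−B additionally loses the fragment's
3'-terminal neutral base); y/d are available but off by default, since
w and a−B suffice to localize a single internal substitution.  Negative-
mode m/z = (M − z·1.00727646688)/z.  Identification scores each candidate
by the matched fraction of its predicted ions (precursor at charge 3 plus
w/a−B at charges 1–2) within a ppm tolerance — presence/absence only, no
intensity weighting, mirroring manual assignment.  Default tolerance
20 ppm (instrument resolution is not otherwise quantified; configurable);
identifications whose top two scores tie within 0.05 are flagged
ambiguous.  The four candidate precursors per strand differ pairwise by
far more than 40 ppm, so the precursor alone already separates them.

## Synthetic data generator

`generate_run` emulates everything between transfection and phosphorimager
readout with a five-parameter model per lesion: bypass probability θ,
product spectrum p on the simplex (plus optional frameshift fractions),
mixing ratios, replicate count, and a per-band multiplicative lognormal
noise exp(σZ).  Expected intensities: competitor band ∝ 1, lesion product
bands ∝ r_lesion·θ·p_M merged by the co-migration rules, control product ∝
r_control.  Defaults are the study design: n = 3 replicates, σ = 0.1,
ratios 1:1 (control), 2:1 (Me/Et/nPr/nBu), 5:1 (iPr/iBu/sBu — the
low-bypass lesions get the higher ratio).  Scenario presets encode
ground truths emulating the reported magnitudes (near-complete bypass
except ~5% for the sBu diastereomers; exclusively T→C miscoding rising
from ~40% for Me through ~80% for Et/nPr to near-100% for the larger
groups).  These presets are declared emulations for exercising the
pipeline, not reproductions of cell-culture measurements.

The generator does **not** model polymerase kinetics, SOS regulation,
repair enzymes, gel background/smearing, band overlap, or isotope
envelopes; passing round-trip tests therefore demonstrates correctness of
the quantification arithmetic and statistics under the declared noise
model, not fidelity to every feature of real gel data.

A note on estimator bias: bypass is a product of four lognormal factors,
so its arithmetic mean over many experiments is θ·e^{2σ²} ≈ 1.02·θ at
σ = 0.1.  At the parameter-recovery operating point (θ = 0.5) this bias is
≈0.5 percentage points, well inside the 2-point recovery check; it grows
toward high θ and σ, which is why aggregation stays the (design-mandated)
arithmetic mean rather than a bias-free geometric mean.

## Numerical and interface choices

* Detection threshold for frameshift bands: 0.5% of lane signal,
  configurable (`--threshold`).
* Zero competitor signal is an error, never a zero bypass value.
* Co-migration is data (TSV keyed by scheme and species), not code.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; a fixed seed fixes every downstream number,
  and pipeline outputs are byte-identical across reruns (floats are
  written with fixed formatting).
* Problem sizes in the shipped property checks: 1000 random digestion
  substrates (30–90 nt), 200 seeded experiments for parameter recovery,
  100 seeded spectra for MS round-trip — sizes at which the Monte-Carlo
  error of each check is far below its tolerance.

## Known limitations

* The true M13mp7(L2) backbone and the competitor genome's own context are
  not reconstructed; both are synthetic fixtures that reproduce the
  assay-relevant fragments.
* No printed m/z values exist to anchor the mass model against the
  original instrument, so MS checks are generate-then-identify round trips
  plus two independent mass oracles (atomic-composition summation and
  Biopython's `molecular_weight`).
* The gel model has no image analysis: band intensities are inputs, as
  produced by a phosphorimager quantification or the generator.
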