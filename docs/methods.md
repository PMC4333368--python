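# Methods

`edgetic` predicts the mechanistic impact of amino-acid substitutions and
post-translational modifications (phospho-Ser/Thr/Tyr, acetyl-Lys) on
biomolecular interactions, by reading changes onto 3D interaction interfaces
through sequence–structure alignments and scoring them with interface
pair-potentials. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic test conditions do and do not
establish.

## Interface model

Structures (PDB or mmCIF text) are parsed into polymer fragments (protein,
DNA, RNA) and ligand instances; each input file is treated as one biological
assembly (no crystal-symmetry expansion). Het groups on a configurable
solvent/additive exclusion list (default `HOH DOD GOL EDO PEG SO4 PO4 CL NA`)
are dropped. Modified residues carried in the polymer (`SEP TPO PTR ALY`) keep
their position and receive the state symbols `Sp`, `Tp`, `Yp`, `Ka`,
extending the residue alphabet to 24 symbols.

Contacts are evaluated on side-chain atoms only (hydrogens ignored; glycine's
CA serves as its surrogate side chain, since it would otherwise never register
a contact):

* **generic** — side-chain atom pairs within **5.0 Å** (for ligand and nucleic
  partners: a protein side-chain atom within 5.0 Å of any partner atom);
* **van der Waals** — C/S side-chain atoms within **4.5 Å** between residues
  with hydrophobic functional aspects
  (`A C F G I L M P V W Y Yp Ka`);
* **electrostatic/H-bond** — N/O side-chain atoms within **5.5 Å** between
  residues with polar/charged aspects
  (`D E H K N Q R S T W Y Sp Tp Yp Ka`); a mixed pair (one functional C/S,
  one N/O) also counts, so that pairs such as Cys–Glu can score.

All thresholds are inclusive. A protein–protein interface requires **≥30**
residue pairs in generic contact; ligand and nucleic interfaces require one.
Interfaces are grouped when member sequences and residue-pair contact sets are
both identical; one representative per group (lexicographically smallest
structure/fragment ids, for determinism) enters all downstream statistics.
Contact conservation across homologous interfaces can be quantified with a
Jaccard index over residue-pair labels (defined as 0 for two empty sets).

## Pair-potentials and direction of effect

For representative interfaces, pair-potentials are log odds

    IPP(a, p) = log( f_obs(a, p) / f_exp(a, p) )

computed per partner axis:

* **residue–residue** — counts over meaningful (vdw or electrostatic)
  contacts, with `f_exp(a,b) = x_a · x_b`, the product of interface molar
  fractions, where `x` is measured over residues participating in each
  interface's contacts;
* **DNA/RNA and chemical classes** — counts over generic contacts, with
  `f_exp(a | class)` the molar fraction of residue `a` among residues of the
  proteins contacting that class (a molar-fraction random model).

Logs are natural (configurable). A pseudocount (default κ = 1 contact,
configurable; κ = 0 reproduces raw log odds) is added to every pair cell over
the symbols present. Chemical classes whose strongest residue preference
stays below 1.0 natural-log unit in magnitude are flagged *unusable* and
contribute nothing to scores — most heterogeneous organic classes fall here,
because a single log-odds column cannot capture molecules that are
simultaneously hydrophobic and charged; metal ions (Zn, Mg, Fe, Mn, Cu) and
the pooled DNA/RNA axis retain informative columns. DNA and RNA are pooled
into one partner class.

The direction-of-effect score of replacing wild-type `wt` by `change` at a
site is

    IE = Σ_contacts ( IPP(change, partner) − IPP(wt, partner) )

with contacts presumed identical to the wild type's, including across
template matches. Positive IE predicts the change enhances the interaction,
negative that it diminishes it. IE is antisymmetric under swapping wild type
and change and additive over contact lists by construction.

The per-site impact score adds, for each interaction type (protein, chemical,
DNA/RNA) with at least one interface hit, the highest |IE| over that type's
partners **plus one**; the plus-one keeps sites with incalculable potentials
(e.g. an unusable chemical class) at a non-zero score. The per-protein score
is the sum over its sites.

### Packaged reference matrix

`data/reference_ipp_synthetic.tsv` is a *synthetic* reference matrix: values
on the ×10 integer grid (stored ÷10, natural-log units) chosen from canonical
interface preferences — opposite charges attract, like charges repel,
hydrophobic and aromatic residues pack, Sp/Tp behave like Asp/Glu, Ka prefers
hydrophobic/aromatic environments — and constrained so that the two canonical
worked examples hold exactly: D→L against two Phe gives +2.4 and R→C against
two Glu gives −3.8. Entries whose display magnitude exceeds 9 (×10 scale) are
stored uncapped and flagged; `display_values()` reproduces the capped integer
view. It is package data for demonstration and testing, not a matrix derived
from any structure corpus.

## Sequence-to-structure mapping and confidence

Queries are aligned to fragment sequences with a local affine-gap aligner
(BLOSUM62, gap open −11, extend −1). Significance is a Karlin–Altschul
E-value with standard ungapped BLOSUM62 parameters (λ = 0.3176, K = 0.134)
over the summed library length; matches with E > 1e−4 are discarded. Per
query position the covering match with the highest percent identity (over
aligned columns, gaps excluded) wins; ties fall to the longer alignment, then
the lexicographically smaller fragment id, so the map is independent of
library order. Intrinsic-disorder scores are an input (any per-residue value
in [0,1]); a residue is flagged disordered when its mean over a centred
11-residue window (truncated at the ends) is ≥0.5.

Confidence calibration builds a gold standard per interaction type: positives
are sites evidenced in contact at ≥90% template identity; negatives are sites
only ever implicated at ≤20% identity and not in the positives (dual-evidence
sites stay positive; the negative set may hide true positives, which makes
the resulting rates conservative). Sweeping thresholds in 1-point steps over
the 20–90% prediction band yields step curves of FPR/TPR, both non-increasing
in the threshold; prediction confidence is the FPR at the largest calibrated
threshold not exceeding the template identity (identities below the range
fall back to the worst calibrated FPR, flagged in the log).

## Pipeline stringency

Interaction records (protein A/B, detection-method class, publication,
direct-physical flag) are deduplicated on the unordered pair. A publication
with ≥300 records is high-throughput; a pair with evidence from ≥2 distinct
publications or methods is high-quality. Filters (direct-physical only,
exclude pairs whose entire evidence is high-throughput, high-quality only,
minimum template identity) only ever shrink the reported set.
Protein–protein interface hits lacking a surviving interaction record are
reported but flagged *structure-only* rather than dropped, mirroring a
low-stringency screening mode. Network edges are labelled by the sign of IE
(enhance > 0, diminish < 0, |IE| ≤ 0.1 neutral, disagreeing changes mixed).

## Accessibility and shuffled nulls

Relative accessibility uses an own rolling-probe (1.4 Å) surface
implementation with quasi-uniform sphere sampling (256 points/atom by
default; deterministic golden-spiral points) and per-element van der Waals
radii. The denominator is the residue's surface in an *extracted tripeptide*
(the residue plus its flanking residues, actual atoms) rather than a
tabulated standard-state maximum: the tabulated values encode the same
convention but are undefined for the pseudo-atom geometries the synthetic
fixtures use. Classes follow fixed thresholds: buried ≤5%, intermediate
>5–≤25%, exposed >25%, and no-3D when no template covers the residue.

Null datasets relocate each change to a random position with the same
wild-type residue — within the same protein (*positions*) or in a random
protein of the dataset (*proteins-and-positions*) — never re-selecting the
original site. The surface-biased variant draws destinations against the
original four-class accessibility histogram (greedy quota with bounded
retries over site orderings), so the class histogram is preserved exactly.
Real-vs-pooled-shuffled overlap with an interface class forms a 2×2 table
tested with a two-sided Fisher's exact test (per-replicate counts are also
retained). Direction-of-effect accuracy is benchmarked as ROC/AUC of |IE|
(or signed IE for single-direction evaluation) against annotated
disabling/enabling/neutral labels. Scores from several predictors can be
combined as normalized averages: per-method min–max to [0,1], then the mean
over methods reporting each mutation (a constant-score method contributes 0.5
and is flagged).

## Synthetic data: what it emulates, and what it does not

The fixture generators are first-class, seeded, self-checking code:

* **complexes** — two extended pseudo-backbones (6 Å residue stride) with one
  side-chain carbon per residue placed to satisfy planted contact distances,
  optional ligands and a nucleic strand at planted distances, optional
  modified residues, and Gaussian coordinate noise (σ = 0.1 Å default). The
  generator re-parses its own output and verifies the planted generic-contact
  set exactly before returning (bounded retries under noise).
* **corpora** — a random query (default 300 residues) and templates at planted
  identities, substitutions spread evenly so local alignments recover the
  planted identity within ~2 points; planted functional sites double as gold
  labels and template interface annotations.
* **change sets** — a configurable fraction of changes at interface positions
  (the rest uniform elsewhere), wild types consistent with the sequences.

Default study conditions used by the statistical suites: enrichment runs use
change sets of n = 200 over ten 200-residue proteins with a 20% interface
fraction, 10 pooled shuffle replicates, and 100 (planted) / 200 (null) seeded
repetitions; direction-ROC permutation checks use 100 replicates of 500
records. These sizes keep every suite desk-scale while leaving the binomial
tolerances meaningful.

Pseudo-atom geometry means the fixtures exercise the distance/atom-name logic
completely but say nothing about real rotamer packing, crystal contacts,
electron-density quality, or charge/coordination chemistry of metals (the
potential model itself ignores ionic charge and coordination shells).
Passing tests establish the machinery — contact rules, counting, calibration
arithmetic, null construction, test statistics — not field accuracy on real
proteomes.

## Limitations

* Corpus-scale published statistics — proteome coverage percentages,
  identity thresholds at fixed confidence (e.g. high confidence near 40%
  identity for protein–protein versus ~56% for DNA/RNA), direction-benchmark
  AUCs on curated human mutation sets, and cancer-dataset functional-site
  counts — depend on specific historical snapshots of structure, sequence and
  interaction databases plus manually curated benchmarks. They are not
  reproducible from synthetic data and are deliberately out of scope; the
  property-based suites above stand in for them. Calibration curves computed
  on a user corpus are inputs to scoring, not universal constants.
* The packaged reference matrix is a constrained synthetic reconstruction
  (see above), not a derived corpus matrix; derive your own from a structure
  collection for production use.
* Homology models are never built; contacts are read through alignments, and
  partner residue identities come from the template structure.
* No biological-assembly generation, SCOP-style domain segmentation (explicit
  residue ranges can stand in for domains), Pfam/HMM assignment, or chemical
  fingerprint clustering (a config map assigns het codes to classes; unknown
  codes fall into an `Organic` catch-all).
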