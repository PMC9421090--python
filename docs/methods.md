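# Methods

## Scope and model

The package evaluates the *foldability signal* carried by predicted-structure
ensembles of engineered protein constructs. The underlying observation is
that structure predictors produce near-native models even for variants that
do not fold experimentally, so the binary "did it fold into a compact model"
is uninformative; the continuous deviation of the models — backbone RMSD
against a reference structure, or RMSD between two predictors' ensembles —
is what correlates with experimental foldability, precipitant ratios and
solubility. The pipeline therefore consists of (1) construct-library
generation, (2) superposition scoring, (3) threshold classification and
stratified contingency summaries, (4) rank correlation and group tests, and
(5) a synthetic generator that stands in for predictor output so the whole
chain is testable end to end.

## Construct generation

**Circular permutants.** For a wild type of length L, construct *n* is
`wt[n..L] + linker + wt[1..n-1]` with linker `GGGGG` by default (any residue
string is accepted; glycine content is not enforced). A Met is prepended
exactly when the new first residue is not Met, or when *n* appears in a
user-supplied *forced-Met* set. The forced-Met set exists because expression
protocols sometimes add a Met even before an existing one (e.g. to protect an
N-terminal Met from methionyl-aminopeptidase); which sites need it is an
experimental fact, not derivable from sequence, so the default is empty.
Construct *n = 1* is the reference construct — wild type plus linker, no
cleavage, no Met — and is included in the enumeration, giving exactly L
constructs. Every construct carries a residue map back to wild-type
numbering (linker and prepended Met map to nothing), which is what the
superposition stage pairs atoms through.

**Insertion mutants.** One residue (Ala by default, configurable) is
inserted between wild-type residues *i* and *i+1* for every internal site
*i = 1..L-1*. Inserting next to a run of the inserted residue is
sequence-degenerate; all sites touching a run produce one product, kept once
under the smallest site index, with a site-to-canonical-site alias table so
experimental tables keyed by either degenerate name join correctly. For a
159-residue protein carrying 13 isolated interior alanines this yields 158
sites and 145 distinct mutants.

## Superposition scoring

Atom pairs come from the construct's residue map (deterministic, preferred)
or from a global affine-gap sequence alignment (BLOSUM62, gap open -10,
extend -0.5) for reference-free comparisons. The default atom set is
{CA, CB, C, O}: CB is not strictly a backbone atom and N is missing, but
this is the set the analysis protocol this package reproduces used, so it is
the literal default; {N, CA, C, O} and {CA} are provided presets. Atoms
absent from either partner (glycine CB, truncated termini) are silently
skipped at pairing time and the retained pair count is always reported.

The fit is the Kabsch SVD solution with the determinant correction enforcing
a proper rotation; inputs with fewer than three pairs or a collinear point
set raise a degenerate-geometry error. `IterativeSuperimposer` adds
outlier rejection: up to `cycles` (default 5) rounds of fit — discard pairs
farther than `reject_factor` (default 2.0) times the current RMSD — refit,
stopping early when nothing is discarded or fewer than three pairs would
remain (the last valid fit is kept). The exact rejection rule of the
original interactive tool is undocumented, so this rule and its defaults are
this package's own convention; cycle-by-cycle RMSDs and rejected pair
indices are recorded in the result so any run is auditable. Rejection can
only lower the retained-pair RMSD, a property the tests assert.

For circular permutants a linear sequence alignment cannot match both
segments of the permuted chain, which is why map-based pairing is the
default for engineered constructs; alignment-based pairing serves the
inter-model comparison, where the two ensembles share one construct
sequence. Results record which pairing produced them.

## Construct records and statistics

Per construct: mean and sample standard deviation (ddof = 1) of the RMSD
over all ensemble models (a single-model ensemble reports sd 0 and a
warning flag); mean Calpha pLDDT (unweighted over residues with a CA, read
from the PDB B-factor column); inter-model RMSD between two predictors'
ensembles — by default the mean over all |A| x |B| cross pairs
(`all_pairs_mean`), since which models the original comparison paired is not
stated; `rank_matched` and `best_pair` are available and recorded.

Classification splits records at a threshold: a named reference construct's
own score, the mean, the median, or a fixed value. Low = score <= threshold
(the reference construct lands in Low; "High" is strictly above, following
the wording of the protocol this reproduces). Group percentages are
foldable/(foldable+unfoldable), rounded half-away-from-zero to one decimal;
totals including unknown-label constructs are emitted alongside, since the
original denominators are ambiguous. Foldability can be derived from
precipitant ratios with the strict rule foldable iff ratio < 0.60; explicit
per-construct overrides always win (they exist for constructs whose
measurements are missing but whose foldability is known on other grounds).
The ratio's directionality is taken exactly as printed in the source
protocol even though its parenthetical definition ("protein in supernatant /
total protein") reads the opposite way; the cutoff rule, not the semantics,
is what the pipeline computes.

Site stratification maps each construct to within_SS/outside_SS through a
per-residue secondary-structure string over the wild type: a permutant takes
the state of residue *n*; an insertion between *i* and *i+1* takes residue
*i+1* (`flank_right`, default), residue *i* (`flank_left`), or is within_SS
only when both flanks are H/E (`both_strict`).

Spearman correlation uses average-rank ties and the t-distribution
approximation for p (scipy); a constant vector yields an undefined rho,
reported as NaN. The unpaired t test is pooled-variance by default with a
Welch flag; two identical constant groups return t = 0, p = 1 by convention.
No multiple-testing correction is applied anywhere — p values are raw, and
reports say so. Solubility analysis sweeps inter-model RMSD cutoffs
(fraction of records with solubility >= 0.60 and mean residue length among
records at or below each cutoff; empty subsets reported as not-applicable)
and summarises solubility quartiles per Low/High group under mean- and
median-threshold splits, using linear-interpolation quartiles (recorded in
the output).

## Synthetic data generator

`make_toy_structure` builds N/CA/C/O (+CB except glycine) backbones by
natural-extension-reference-frame placement from ideal bond lengths and
angles, with canonical dihedrals: helix phi = -57, psi = -47; strand
phi = -119, psi = +113; coil phi ~ U(-160, -60) and psi drawn from the
broad beta/alpha basins (60/40), all from the seed.

`simulate_model_ensemble` emulates a predictor's five-model ensemble: each
model is the reference plus a smooth displacement field — a sum of 3
low-frequency sinusoidal modes along the chain with random directions and
phases, weighted 1/m — plus i.i.d. jitter at 5% of the scale. The total
displacement is rescaled by fixed-point iteration so the superposed backbone
RMSD to the reference equals the requested deviation essentially exactly;
the field is chain-correlated rather than i.i.d. per atom so the outlier
rejection behaves as it does on real models. Per-residue pLDDT is
clip(100 - 2.0 x local displacement + N(0, 2)), i.e. only weakly coupled to
the deviation by default — deliberately, because predictor confidence did
not separate foldable from unfoldable constructs in the data this emulates —
and a zero deviation yields exact copies at pLDDT 100.

`simulate_construct_library` generates a full permutant study at the default
conditions: wild-type length 100 (hence 100 constructs), 5 models per
ensemble per predictor, per-construct deviations ~ Gamma(shape 2,
scale 0.75 A) (mean 1.5 A, range roughly 0.3-4 A, matching the spread of
mixed-quality predictor ensembles); P(foldable) = logistic(-3.0 x
(deviation - 1.5 A)); precipitant ratio = clip01(0.2 + 0.25/A x deviation +
N(0, 0.08)); solubility = clip01(0.9 - 0.2/A x deviation + N(0, 0.08)).
Ensembles "A" and "B" share the construct's true deviation but use
independent displacement fields, so the A-B inter-model RMSD grows with the
deviation. Model ensembles are construct-shaped: mapped positions reuse the
perturbed wild-type residue's atoms in construct order through the residue
map, while linker/Met positions receive deterministic placeholder
coordinates that are never paired during map-based scoring — the scoring
path exercised end to end is exactly the one real data would take. All
randomness flows from one seed through spawned seed sequences; identical
configs reproduce byte-identical FASTA/PDB/CSV.

What the generator does *not* emulate: physically realistic alternative
folds (perturbations are smooth deformations of one topology, not
misfolding), side chains beyond CB, predictor-specific error structure, or
any coupling between a construct's sequence change and its deviation (the
deviation is planted, not caused). Passing recovery tests therefore show
that the pipeline's statistics faithfully detect a monotone
deviation-foldability association when one exists — not that real predictor
ensembles carry one.

## Numerical and design choices

* Percentages: half-away-from-zero to one decimal, via exact decimal
  arithmetic on the printed value; the source protocol itself rounds
  inconsistently at the last digit, so comparisons allow +-0.1.
* Quartiles: linear interpolation (numpy default), recorded in output.
* Tie rule: Low = score <= threshold, everywhere.
* Kabsch degeneracy: scatter-matrix rank < 2 (collinear/coincident) raises
  rather than returning an arbitrary rotation.
* The deviation calibration targets the single-pass superposition RMSD over
  all backbone atoms; scored RMSDs over the {CA, CB, C, O} subset with
  rejection may differ by a few percent, which the stochastic tolerances in
  the tests reflect.
* PDB serialisation is delegated to gemmi (fixed columns, coordinates to
  3 decimals, B-factors to 2, hybrid-36 beyond the serial field width);
  B-factors are stored single-precision, so round trips are asserted at the
  format's own precision.
* Problem sizes in the test and acceptance studies (wild-type length 100,
  5 models per ensemble, 100 replicates) are the generator's default study
  conditions; smaller toy sizes appear only in unit tests of exact
  contracts.

## Known limitations

* Single chain, first model only; ligands, hydrogens and multi-chain
  assemblies are out of scope.
* The insertion-site/secondary-structure flank rules assume the wild-type
  numbering; constructs whose sites fall outside the provided SS string
  raise.
* `pair_by_alignment` is a linear global alignment and will not recover the
  two-segment correspondence of a circular permutant against the wild type;
  use the residue map for that (the default).
* The label/solubility links are monotone by construction; the pipeline's
  recovery statistics say nothing about non-monotone or confounded real
  associations.
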