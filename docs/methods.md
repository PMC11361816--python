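# Methods

## Scope and model

`ddikit` treats the reliability of an inferred domain–domain interface
(DDI) type as a binary outcome — a curator would either approve it as a
bona fide mode of protein binding or not — and models that outcome with a
logistic regression on interface evidence:

logit P(approved) = β₀ + Σᵢ βᵢ xᵢ

The covariates are per-type summaries anchored to the single
highest-3did-score interface of the type: the 3did z-score (contact-count
significance against random expectation), the raw 3did score, the number of
residue–residue contacts, counts of structures with interchain and
intrachain interfaces, the DockQ of an AlphaFold fragment model against the
representative resolved structure (an ingested column — this package never
runs AlphaFold or computes DockQ), and the interface disorder fraction.
Coefficients are maximum-likelihood estimates via iteratively reweighted
least squares (statsmodels GLM, binomial family); `exp(βᵢ)` is the odds
ratio per covariate unit.

Model assumptions worth keeping in mind: independence of benchmark rows
(each DDI type enters once), linearity of the log-odds in the covariates,
and outcome labels that are themselves a (careful but fallible) human
judgment.

## Classification of DDI types

An interface is intrachain when both domains sit on the same chain of the
same structure. A type is *intrachain-only* when every supporting interface
is intrachain; any interchain evidence anywhere disqualifies that label. A
type whose every interchain interface joins two chains of the same protein
accession is *homo-protein-only*; one heterodimeric interface makes it
*hetero interchain*. Only the hetero interchain class is carried forward as
a candidate set: intrachain and homodimer-only evidence cannot be separated
from intramolecular geometry or crystal packing without manual curation.
Chains that cannot be resolved to a protein accession abort classification
loudly rather than defaulting to any class, because a silent guess would
contaminate the candidate set.

Per structure, the representative interface is the interchain interface
with the highest 3did score, regardless of intrachain scores; only
structures without interchain interfaces are represented by their best
intrachain interface. Score ties break lexicographically on the chain-id
pair, then on file order, so regression outputs are stable.

## Interface geometry and disorder

A residue is an interface residue when any of its heavy atoms lies within
10 Å of any heavy atom of the partner chain. All non-hydrogen atoms count,
side chains included; hydrogens are ignored where present because structure
files vary in hydrogen content. For alternate locations the
highest-occupancy conformer is used, giving deterministic single-conformer
geometry. Detection uses a k-d tree; tests compare it against an exhaustive
all-atom-pairs oracle.

Structure residue identifiers are opaque author-numbering tokens until a
SIFTS-style residue-level mapping translates them to 1-based UniProt
sequence indices; unmapped residues are returned explicitly, never dropped.
The interface disorder fraction is the share of interface residues whose
IUPred-style score is strictly above 0.4, computed per chain and pooled
over the interface. An empty interface yields a missing value with a
warning — reporting 0 would masquerade as "fully ordered". Where a single
per-type disorder value is needed, the maximum of the two per-chain
fractions of the representative structure is used (the more disordered side
is the red flag).

## Model selection, validation and inversion

- **Stepwise reduction** is backwards elimination under AIC: at each step
  the removal that lowers AIC most is applied until no removal improves it.
  All fits within a step use the complete-row set of the current variable
  pool so AICs are comparable. AIC retains a pure-noise covariate whenever
  its likelihood-ratio statistic exceeds 2, i.e. with probability
  P(χ²₁ > 2) ≈ 0.157 — the test suite checks the removal rate against that
  closed form, not against an arbitrary target.
- **Leave-one-out cross-validation** scores each labeled row with a model
  fit on the remaining n−1 rows; folds are the rows themselves, so the
  procedure has no randomness. ROC curves, AUC and the Youden threshold
  (maximizing sensitivity + specificity − 1; ties broken toward higher
  specificity) are computed on the out-of-fold probabilities with
  "approved" as the positive class.
- **Nested comparisons** use the likelihood-ratio statistic
  2(ℓ_big − ℓ_small) on a χ² with df equal to the parameter difference, and
  require both fits on the identical row set; comparing fits on different
  listwise-deletion sets is a usage error, not a silent approximation.
- **Calibration** is assessed by Hosmer–Lemeshow over deciles of predicted
  probability (bins with degenerate expected counts are merged with their
  neighbor and the merge count reported; df = groups − 2) and by decile
  calibration tables (observed approval fraction per predicted-probability
  decile; constant predictions collapse into one visible bin).
- **Bootstrap AUC comparison** resamples rows jointly (paired) over the two
  out-of-fold probability vectors and takes a two-sided p from the normal
  approximation to the bootstrap distribution of the AUC difference; a
  model compared with itself gives p = 1 by construction.
- **Inversion**: with the minimal model (intercept + z-score),
  z(p) = (logit(p) − β₀)/β₁ turns a desired approval probability into a
  z-score screening cutoff; forward and inverse compose to identity within
  1e-9.

Numerical safeguards: linear predictors are clipped at ±36 before
exponentiation (this affects nothing at reported precision); rank-deficient
designs raise an error naming the offending columns rather than fitting on
a pseudo-inverse; perfect or quasi-separation is flagged on the fit, never
silently returned as a converged estimate.

## Network scanning, randomization and boundary refinement

A PPI edge (a, b) is predicted to be mediated by high-confidence type
(X, Y) when a carries a Pfam match to X and b to Y or vice versa; homotypic
types (X, X) need the match on both partners, and a self-edge needs both
matches on its one protein. Types involving the intermediate-filament rod
domain (PF00038) are excluded by default — its coiled-coils pair
promiscuously in keratin-rich interactome data and would dominate the
prediction set; the exclusion list is configurable. When several matches of
the same family occur on a protein, the lowest-e-value (then
highest-score, then first) match supplies coordinates.

Enrichment over chance is measured against degree-preserving
randomizations: repeated double-edge swaps (10 × |edges| attempts by
default, a standard mixing heuristic), with self-loops held fixed because a
swap involving a loop could change degrees. The empirical p-value uses the
add-one correction (1 + #{null ≥ observed})/(n_random + 1), so a finite
null sample never reports p = 0.

Pfam matches often truncate the structural fold, which hurts
fragment-based complex modeling. Boundary refinement therefore widens each
match side independently: while the mean pLDDT of the 10 residues just
inside the current boundary is ≥ 80 — sustained high predicted confidence
marks ordered structure — the boundary steps outward one residue, stopping
when the mean drops below 80 or the terminus is reached. Near termini the
mean is taken over the residues available (a truncated window avoids index
errors without changing behavior elsewhere). The refined interval always
contains the input interval, raising the cutoff never widens it, and the
procedure terminates within protein-length iterations. Exported fragment
pairs are FASTA records whose headers encode accession, family and refined
coordinates, with the sequence equal to the 1-based inclusive slice.

## Key parameters

| parameter | default | units | meaning |
|---|---|---|---|
| contact cutoff | 10 | Å | heavy-atom distance defining interface residues |
| disorder threshold | 0.4 (strict >) | score | IUPred-style level above which a residue counts as disordered |
| pLDDT cutoff | 80 | pLDDT | order/disorder transition level for boundary extension |
| pLDDT window | 10 | residues | boundary-interior window averaged per step |
| z-score cutoff | 4.47 | 3did z | screening default at 80% expected approval probability |
| excluded families | PF00038 | — | rod-domain filter for network predictions |
| null networks | 100 | — | degree-preserving randomizations per enrichment |
| swap factor | 10 | ×edges | attempted double-edge swaps per randomization |

All are configurable via function arguments, the YAML config, or CLI flags,
with precedence CLI flag > config file > default.

## Synthetic study conditions

The generators encode the study conditions under which the pipeline is
validated:

- **Flat files**: 45 DDI types (10 intrachain-only, 20 homo-protein-only,
  15 hetero interchain), 1–3 structures per type, 5–20 contacts per
  interface, with interchain-classed types sometimes carrying an additional
  intrachain interface in the same structure so the "any interchain
  evidence disqualifies intrachain" rule is exercised.
- **Benchmark tables**: 80 labeled rows, 5 of which involve an
  engineered-scaffold family (Ankyrin PF00023 / V-set PF07686), matching
  the curated benchmark's composition. Covariates are shaped like the real
  annotations — right-skewed positive z-scores (gamma(2, 1.5) + 0.5),
  [0, 1]-bounded DockQ and disorder fractions (beta), contact counts
  increasing with z-score — and labels are Bernoulli draws from a planted
  model with intercept −3 and coefficients 0.7 (z-score), 2.5 (DockQ) and
  −2.5 (disorder), chosen once to give a realistic approved/nonapproved mix
  at benchmark scale.
- **Networks**: 200 proteins, 400 edges by default, with half the edges
  planted to carry a complementary high-confidence pair and a 5% per-pool
  background match rate so chance pairings exist; optionally an exact
  degree sequence via Havel–Hakimi construction.
- **Profiles**: one ordered plateau (pLDDT 95) per protein on a baseline of
  40, optional Gaussian noise, with disorder anti-correlated by
  construction.
- **Toy structures**: two chains on parallel lines, 20 Å residue spacing,
  planted contact pairs at 6 Å and everything else ≥ 50 Å off-line, with
  optional multi-atom residues jittered within 0.8 Å.

What these synthetic conditions do *not* emulate: real Pfam match quality
and boundary error distributions, the correlation structure of real 3did
scores across types, crystal-contact geometry, realistic folds or degree
distributions of curated interactomes. Passing tests therefore demonstrate
that the machinery is correct under known ground truth — not that the
fitted synthetic coefficients or AUCs transfer to real 3did content.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
coefficient recovery at n = 500–1000 rows, coverage and null-uniformity
studies over 200 and 1000 replicates, 100 randomizations of a
200-node/400-edge network, 50 toy structures against the exhaustive
geometry oracle, and 100 profile refinements against the step-by-step rule
simulation. The complete suite finishes in well under a minute on one CPU.

## Known limitations

- Reproducing the published model statistics (LOOCV AUCs 0.795/0.807/0.772,
  nested p-values 0.007/0.336, the 2.3 → 33% and 4.47/5.30 cutoff
  calibration) requires the authors' curated 80-type benchmark table as an
  input file; it is not redistributable here, and the corresponding
  acceptance test fails with an explicit message when the file is absent.
- Database census counts (how many types are intrachain-only, homodimeric,
  or hetero interchain) and interactome application counts are properties
  of specific external data releases; the package exercises those code
  paths on synthetic data only.
- DockQ, pDockQ and any AlphaFold outputs are strictly ingested columns;
  the package neither runs structure prediction nor evaluates models.
- The logistic model is intentionally plain: no regularization, no
  interactions, no multi-class labels. With 80-row benchmarks, richer
  models are not identifiable anyway.
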