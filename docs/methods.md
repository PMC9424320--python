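# Methods

This note records the models implemented by `pathranker`, their assumptions,
the defaults that matter, and the choices made where the design was open.

## Enriched pathway documents

Pathways are SBML Level 3 Version 1 documents using the `groups` package.
Content that standard SBML has no slot for — SMILES/InChI/InChIKey on
species, reaction-rule id, template-reaction id, rule (enzyme-availability)
score, per-reaction ΔG′, pathway-level properties — lives in a dedicated
annotation namespace (`https://pathranker.dev/ns/annotation/v1`), one XML
element per field inside the standard `<annotation>` container, so any
compliant SBML reader parses the files unchanged. The schema (namespace URI
and element names) is defined by this package; it deliberately captures the
same *content* as the enriched files produced by pathway-design pipelines
without claiming to reproduce any external wire format.

Determinism: species and stoichiometric references are emitted in sorted
order, stoichiometries as decimal strings with at most six significant
digits, so write→read→write is byte-stable — the round-trip property the
test suite checks.

Group semantics: `rp_pathway` lists the heterologous reactions in pathway
order (substrate side first); `rp_fba_ignored_species` the species excluded
from FBA mass balance; `rp_thermo_substituted_species` the species whose
thermodynamic identity came from a user substitution.

## Completion and enumeration

A master pathway is an ordered list of rule-level transformations; each
transformation may reference several reaction rules, each rule generalises
one or more full template reactions. Completion creates one candidate
reaction per (rule, template) pair: the transformation's own species plus
every template participant whose structure-based identity (InChIKey when
available, else id) matches none of them — the cofactors — at template
stoichiometry. Enumeration is the Cartesian product of per-transformation
alternatives.

Two pathways are duplicates when their reaction *multisets* are equal under
that species identity with stoichiometries compared at 1e-9. Output order is
lexicographic by reaction-id tuples. The optional "keep top N per master
pathway" cut ranks by descending mean rule score with ties broken by pathway
id; the ranking criterion is this package's choice, exposed as `--keep-top`
and off by default, because no canonical criterion exists for it.

## Fraction-of-reaction FBA

Assumptions: steady state, a designated biomass reaction, flux bounds in
mmol·gDCW⁻¹·h⁻¹. The procedure: (1) maximise biomass, record optimum B;
(2) set both biomass bounds to f·B; (3) maximise an irreversible target sink
(`SINK_<target>`, bounds [0, 1000] — the standard export convention, chosen
here since nothing forces reuse of an existing exchange); (4) restore every
modified bound. The default f = 0.75 is this package's default — a burden
level that leaves a meaningful production margin while forcing substantial
growth; it is exposed as `--fraction` and swept in tests, and no particular
value is canonical.

Orphan species — pathway species absent from the chassis that appear on only
one side of the pathway's combined stoichiometry — can never be balanced by
any flux distribution, so they are removed from mass balance and recorded in
`rp_fba_ignored_species`. Species produced *and* consumed within the pathway
are true intermediates and are kept. Only the optimal objective value is part
of the contract: under alternate optima the individual fluxes of other
reactions are solver-dependent and deliberately unreported.

Numerics: COBRApy/GLPK defaults; test assertions compare objectives at 1e-6
absolute. An independently coded dense-matrix LP (scipy HiGHS) over the same
stoichiometry serves as the oracle on small models.

## Pseudo-reaction thermodynamics

The pathway ΔG′ is evaluated on the net reaction from chassis substrates to
target. Intermediates are species produced by one pathway reaction and
consumed by another and not present in the chassis species set; chassis
species are never constrained to cancel. With A the intermediates-by-
reactions matrix and c the indicator of target-producing reactions, the
multipliers solve

    min cᵀx  s.t.  A·x = 0,  x ≥ 1   (scipy linprog, HiGHS, default tolerances).

The objective sense is minimisation: the constraint set is a cone truncated
at x ≥ 1, closed under uniform up-scaling, so maximisation is unbounded;
minimisation yields the componentwise-smallest feasible multipliers (the
test suite verifies minimality by grid search). Multipliers are continuous —
fractional values are expected and correct. Net coefficients below 1e-9 are
dropped; an infeasible cancellation raises an error naming the intermediates.
A single-reaction pathway short-circuits to multiplier 1.

Formation energies come from a provider behind a two-method interface
(`resolve`, `dg_of`); a TSV-backed table implementation ships with the
package. The lookup cascade stops at the first hit: species id → InChIKey →
InChI → SMILES → first compound listed under the InChIKey connectivity
block (sorted provider keys, first taken) → user substitution. A reaction
with any unresolved, unsubstituted species has no ΔG′; the pathway ΔG′ is
absent whenever the net reaction has one. Reaction ΔG′ = Σ products·ΔG′f −
Σ reactants·ΔG′f; uncertainties propagate in quadrature when present. pH and
ionic-strength transforms are the provider's concern, not this package's.

## Scoring

Feature vector per pathway (order-free by construction): chassis taxon id;
pathway ΔG′; fraction-of-reaction target flux; mean rule score; summed
per-reaction ΔG′; reaction count; elementwise sum of per-reaction Morgan
count fingerprints (radius 2, folded to 4096 positions — the radius is this
package's choice, the standard ECFP4-equivalent setting); plus two binary
missingness flags. Missing ΔG′ or flux is imputed with 0 and flagged so that
pathways with unresolved species remain scoreable. A reaction fingerprint is
the elementwise sum of the fingerprints of all its substrates and products.

The global scorer is an XGBoost classifier with maximum tree depth 1000 and
learning rate 0.3, everything else at library defaults, wrapped as a
scikit-learn estimator. Metrics come from stratified 4-fold cross-validation
(seeded, default 42): accuracy at the 0.5 probability threshold and false
positive rate pooled over folds.

Direct score = 1/n_reactions + minmax(−ΔG′) + minmax(mean availability) +
minmax(flux), normalised across the candidate set for one (target, chassis)
pair. When an axis is constant across the set its normalised value is 0.5
for every candidate (any constant preserves the ordering; 0.5 keeps the
component inside [0,1]).

Top-k recovery: within each (target, chassis) group, ranks are taken over
*distinct* score values, ties sharing a rank; a group counts as recovered
iff its best-scoring reference pathway sits within the top k distinct
scores. The reported number is the fraction over groups that contain a
reference.

## Literature matching

Step similarity = 0.5 · Jaccard over the union of main substrate/product
identity keys (InChIKey connectivity block, falling back to species id)
+ 0.5 · best pairwise EC agreement counted to three levels. When neither
side carries EC numbers the structural term carries full weight, so a
pathway always matches itself at 1.0. "Main" species are the non-cofactors;
the cofactor list (common currency metabolites by MetaNetX id and plain
name) is configurable. Predicted reactions are assigned to reference steps
by a dynamic program over order-preserving injective assignments maximising
total similarity; the pathway score divides that total by the longer of the
two pathways. A predicted pathway is labelled a literature pathway iff its
score is strictly above 0.5. These weights and the normalisation are this
package's definition — only the threshold semantics and the identity
criterion are externally anchored.

## Construct design

Designs enumerate promoters × per-slot linker assignments × CDS orders on
one backbone: |P|·|R|^G·G! with permutation on, verified against brute force
for all small registries. Output order is lexicographic over sorted part
ids; `design_id` concatenates promoter and per-slot `cds.linker` tokens, so
it is stable across runs and unique under (promoter, slots). The full
theoretical set is always emitted; an optional exclusion list supports
externally curated removals. The assembly-plan CSV dialect is
`design_id,backbone,promoter,slot1_linker,slot1_cds,...`.

## Synthetic fixtures

`pathranker.synth` generates every test input. The toy chassis is a linear
chain — one uptake (bound 10), conversions, one biomass reaction — feasible
by construction with biomass optimum 10. Labelled pathway sets emulate the
*structure* of a pathway-scoring training corpus: candidate pathways of 2–5
reactions attached to a chassis metabolite, a positive fraction defaulting
to 754/7919 ≈ 0.095 (the class balance of the benchmark corpus this mirrors),
and a planted effect on positives — pathway ΔG′ lower, target flux and rule
scores higher, each shifted by `effect_size` noise standard deviations
(σ_ΔG = 20 kJ/mol, σ_flux = 0.5, σ_avail = 0.1; negatives centred at
0 kJ/mol, 1.0, 0.5). Cofactors are consumed/produced in disjoint one-way
pairs so they are FBA orphans and never pseudo-reaction intermediates.

Synthetic species carry real SMILES from a fixed 32-molecule alkane/alcohol
alphabet (fingerprints and InChIKeys are computed, not mocked); species
without structures get a deterministic SHA-256-derived key in the 14-10-1
InChIKey pattern. Classifier tests on these sets therefore demonstrate
recovery of a *planted pathway-level* signal under realistic feature noise —
they do not demonstrate that real engineered-pathway validity is learnable,
since the fingerprint features here carry no label information and real
chemistry is absent. Default problem sizes (hundreds of pathways, 4-fold
CV) are chosen so the full suite runs on a laptop in minutes.

## Known limitations

- The enriched-SBML annotation schema is package-defined; files from other
  pipelines with different custom namespaces parse as plain SBML only.
- The matching score is an anchored re-design, not a reproduction of any
  published supplementary algorithm; absolute score values are comparable
  only within this package.
- Thermodynamics requires a formation-energy provider; no component-
  contribution estimator is bundled.
- Alternate FBA optima leave non-objective fluxes unspecified.
- The pseudo-reaction LP asserts solution uniqueness only on fixtures;
  degenerate pathways with multiple minimal multiplier vectors report the
  solver's vertex.
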