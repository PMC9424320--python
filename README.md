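# pathranker

Tools for evaluating, scoring and ranking candidate heterologous metabolic
pathways in a chassis organism, and for enumerating the combinatorial genetic
constructs that encode a chosen pathway.

When a retrosynthesis engine proposes dozens of candidate routes from a host's
native metabolites to a target compound, a metabolic engineer needs to know
which routes are worth building. `pathranker` covers that decision pipeline:

- **Pathway completion** — expand rule-level "master" pathways into concrete
  reaction pathways by forking over reaction rules and their template
  reactions, re-adding cofactors and removing structural duplicates.
- **Fraction-of-reaction FBA** — the maximal target production flux while
  biomass flux is pinned to a fraction of its unconstrained optimum, i.e.
  production under a stated growth burden.
- **Pseudo-reaction thermodynamics** — the pathway ΔG′ computed on the net
  reaction from chassis substrates to target, obtained by solving a linear
  program for stoichiometric multipliers that cancel every intermediate.
- **Scoring** — a direct (non-learned) score summing four normalised criteria,
  and a learned global score from a gradient-boosted classifier over pathway
  and reaction features (Morgan-fingerprint reaction representations included),
  with top-k recovery of reference pathways as the benchmark metric.
- **Literature matching** — similarity of a predicted pathway to a curated
  reference route (main substrates/products + EC agreement), with the strict
  0.5 labelling threshold.
- **Construct design** — BASIC-style combinatorial enumeration
  (promoter × RBS-linker assignment × CDS permutation on a backbone) and an
  assembly-plan CSV.

Pathways travel as enriched SBML Level 3 documents: standard SBML plus a
dedicated annotation namespace for structure identifiers (InChI, SMILES,
InChIKey) and rule provenance, and the SBML `groups` package for pathway
membership (`rp_pathway`) and bookkeeping sets (`rp_fba_ignored_species`,
`rp_thermo_substituted_species`). Standard SBML readers parse these files
unchanged.

## The core computations

**Fraction-of-reaction FBA.** For a merged model with stoichiometric matrix
S, first solve max v_biomass s.t. S·v = 0, l ≤ v ≤ u; record the optimum B.
Then fix both biomass bounds to f·B (default f = 0.75) and solve
max v_sink for an irreversible target sink. All modified bounds are restored
afterwards. Pathway species that the chassis lacks and that appear on only
one side of the pathway ("orphans") are excluded from mass balance and
reported.

**Pseudo-reaction multipliers.** With A the intermediates-by-reactions matrix
(products positive, reactants negative) and c the indicator of
target-producing reactions, solve

    min cᵀx   s.t.  A·x = 0,  x ≥ 1.

The feasible set is closed under uniform up-scaling, so minimisation selects
the componentwise-smallest multipliers. The pathway ΔG′ is then the formation
energy difference over the multiplier-weighted net reaction, using a pluggable
formation-energy provider with a first-hit lookup cascade
(id → InChIKey → InChI → SMILES → InChIKey connectivity block → user
substitution).

**Global score.** XGBoost classifier (max tree depth 1000, shrinkage 0.3,
other hyperparameters at library defaults) over a feature vector of chassis
taxon id, pathway ΔG, target flux, reaction count, mean enzyme-availability
score, summed reaction ΔG, and the elementwise sum of per-reaction
4096-position Morgan count fingerprints, where
fingerprint(reaction) = fingerprint(substrates) + fingerprint(products).
Metrics are reported from stratified 4-fold cross-validation at a 0.5
threshold. The estimator (`GlobalScoreClassifier`) follows the scikit-learn
fit/predict contract and composes with sklearn model selection.

**Direct score.** Sum of (i) 1/pathway length, (ii) min-max-normalised −ΔG,
(iii) normalised mean availability, (iv) normalised target flux, normalised
across the candidate set for one (target, chassis) pair.

## Worked example

```python
from pathranker.records import PathwayRecord, ReactionRecord, Species
from pathranker.thermo import build_pseudo_reaction
from pathranker.construct import enumerate_constructs, lycopene_registry
from pathranker.fba import fraction_of_reaction_fba
from pathranker.synth import make_toy_chassis, make_pathway_set, FixtureSpec

# A 3-reaction pathway: MNXM* are chassis metabolites, CMPD3/CMPD4 are
# pathway intermediates that must cancel, TARGET is the product.
reactions = [
    ReactionRecord(id="Rxn1",
        reactants={"MNXM188": 1, "MNXM4": 1, "MNXM6": 1, "MNXM1": 3},
        products={"CMPD4": 1, "CMPD3": 1, "MNXM13": 1, "MNXM15": 1, "MNXM5": 1}),
    ReactionRecord(id="Rxn2", reactants={"MNXM4": 1, "CMPD3": 2},
        products={"MNXM1": 2, "TARGET": 1}),
    ReactionRecord(id="Rxn3", reactants={"MNXM4": 1, "MNXM6": 1, "CMPD4": 3},
        products={"MNXM13": 1, "MNXM5": 1}),
]
species = {s: Species(id=s) for r in reactions for s in r.species_ids}
pathway = PathwayRecord(id="demo", reactions=reactions,
                        target_id="TARGET", species=species)
chassis_species = {s for s in species if s.startswith("MNXM")}

x, net = build_pseudo_reaction(pathway, chassis_species)
print("multipliers:", [float(v) for v in x])
print("net reactants:", {k: float(v) for k, v in sorted(net.reactants.items())})

chassis = make_toy_chassis(4, seed=1)
p = make_pathway_set(FixtureSpec(seed=2, n_pathways=1, positive_fraction=0.5),
                     chassis)[0][0]
res = fraction_of_reaction_fba(chassis, p, fraction=0.5)
print("biomass optimum:", res.biomass_optimum,
      "| target flux at 50% biomass:", res.target_flux)
print("constructs:", len(enumerate_constructs(lycopene_registry(), permute=True)))
```

prints

```
multipliers: [3.0, 1.5, 1.0]
net reactants: {'MNXM1': 6.0, 'MNXM188': 3.0, 'MNXM4': 5.5, 'MNXM6': 4.0}
biomass optimum: 10.0 | target flux at 50% biomass: 5.0
constructs: 96
```

The multipliers (3, 1.5, 1) weight the three reactions so that CMPD3 and
CMPD4 cancel exactly while every multiplier stays ≥ 1; the net reaction then
consumes 5.5 MNXM4 and 4 MNXM6 per 1.5 TARGET. The toy chassis can fix 10
flux units of biomass, so pinning biomass at 50% leaves 5 units of uptake for
the pathway's target sink. The lycopene-style registry (2 promoters, 2 RBS
linkers, 3 CDS, gene-order permutation on) expands to 2·2³·3! = 96 constructs.

A command-line interface mirrors the library:
`pathranker {convert,complete,fba,thermo,score,train,match,design,synth}`
(see `pathranker --help`).

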