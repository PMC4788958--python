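# odemerge

Semi-automatic **horizontal integration of kinetic ODE models** in SBML:
identify the overlap of two annotated models, merge them under a
parameter-source policy, test consistency of the merged model against the
originals' data with a chi-square-per-point criterion, and restore
consistency by goal-driven reparameterization.

The workflow has three stages:

1. **Preparation** — load and validate SBML (Level 2/3), extract each
   element's semantic identity (MIRIAM RDF URIs + SBO term + a structured
   display name parsed under a fixed naming convention), and harmonize
   units between the two models.
2. **Structural integration** — compute an automatic, annotation-based
   matching of compartments/species/reactions/parameters, support manual
   post-editing (add/remove/confirm matches, attach conflict flags),
   classify conflicts (modification sites, compartments, states, kinetics,
   modifier-vs-reactant, level of detail), and build a merged model in
   which every overlap element appears once, parameterized from model A or
   model B per policy.
3. **Behavioral integration** — generate synthetic datasets by simulating
   the originals under step stimuli (errors: 10 % relative + 5 % of curve
   maximum), compute per-side pooled chi2/N of the merged model with the
   other side's inputs zeroed, judge consistency (both sides strictly
   below one) against a declared integration goal, select refit candidates
   that cannot disturb the preserved side, and re-estimate them by
   multi-start trust-region least squares over all datasets simultaneously.

## Library quick tour

```python
from odemerge import (
    load_model, harmonize_units, auto_match, classify_conflicts,
    merge_models, MergePolicy, IntegrationGoal, check_consistency,
)
from odemerge.workflow import build_synthetic_datasets
from odemerge.refit import FitProblem, candidate_free_parameters, fit_parameters

a, b = load_model("model_a.xml"), load_model("model_b.xml")
a, b, unit_log = harmonize_units(a, b)
matches = classify_conflicts(auto_match(a, b), a, b)
merged = merge_models(a, b, matches, MergePolicy(default_source="A"))
```

A fully synthetic, download-free test bed is built in
`odemerge.fixtures.generate_toy_pair`: two step-stimulated receptor
branches converging on a shared phosphorylation cascade, with controllable
overlap size and a divergence factor on the overlap parameters, plus the
ground-truth match set.

## CLI

```bash
odemerge validate model.xml
odemerge match a.xml b.xml --out match.json --table match.tsv [--edits edits.json]
odemerge merge a.xml b.xml match.json --source A --out merged.xml
odemerge check config.yaml        # pipeline up to the consistency check
odemerge refit config.yaml        # including refit/check iterations
odemerge run   config.yaml        # full workflow
```

`config.yaml` holds model paths, the policy, the goal
(`preserve-A` / `preserve-B` / `both`), pre-supplied manual match edits,
observables, the step-stimulus dataset plan, fit settings and the seed; see
`odemerge.workflow.WorkflowConfig`. Every stage writes its artifact
(validation reports, match table, merged SBML + provenance sidecar,
consistency reports, fit results) into the configured output directory.

## Case study and acceptance report

The structural/behavioral case study integrates two curated signaling
pathway models (EGF- and NGF-driven Akt pathways, BioModels accessions
BIOMD0000000262 / BIOMD0000000263). Those third-party files are not
redistributed here: drop the two SBML files into `data/` (see
`data/README.md`) to enable the case-study tests in
`tests/test_acceptance.py` and the full acceptance report.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script rebuilds the case study from the accession files, recomputes
the structural counts, the pre-refit per-side chi2/N values, and the
post-refit values of both the restricted and the full reparameterization,
and writes them as JSON. When the accession files are absent it writes an
empty report and explains why on stderr; the download-free property suite
(merge count conservation, exact planted-overlap recovery, chi-square
self-consistency and scale equivariance, parameter recovery, preserved-side
invariance, simulator closed-form checks) is then the acceptance surface.
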