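# pgccscreen

Discovery stack for screening compounds against **polyploid giant cancer
cells (PGCCs)** — large, often chemotherapy-resistant tumour cells whose
persistence after treatment is linked to relapse. The package covers the
full loop of a phenotypic anti-PGCC campaign on synthetic data:

1. **Image quantification** — segment nuclei in three-channel plate images
   (Hoechst for nuclei, calcein-AM for live cells, ethidium homodimer-1 for
   dead cells), gate viability, and call PGCCs by nuclear size against a
   control-calibrated area threshold.
2. **Screen analytics** — normalize per-well PGCC and total live-cell counts
   to in-plate control wells, transform the normalized PGCC fraction to a
   log2 response, and bin compounds into hit categories (PGCC reduced
   2×/10×, PGCC enriched, total inhibited, dual inhibitor).
3. **Molecular features** — MACCS (166), a PubChem-layout substructure key
   dialect (881) and ECFP6 (1024 bits) fingerprints, all seven non-empty
   concatenations, plus 1536/3072-dimensional text embeddings of compound
   descriptions: nine feature sets in total.
4. **Model benchmark** — seven regressor families (ridge, SVR, random
   forest, histogram gradient boosting, decision tree, SGD, MLP) on each
   feature set under repeated 10-fold cross-validation with a single shared
   fold plan, scored by per-fold Pearson correlation.
5. **Stacked ensemble** — an ordinary-least-squares meta-learner combining
   the best structure-based and best description-based models, fitted on
   out-of-fold predictions, with standard errors, p-values and a paired
   t-test against each base.
6. **Virtual screening** — rank an external library by predicted response
   (most negative = strongest predicted PGCC reduction) and select the
   top k, with a completeness/exclusion audit.

Everything runs offline on synthetic fixtures: plate images with planted
nucleus geometry, a fragment-grammar compound generator with a planted
structure–activity relationship (SAR), and a deterministic mock embedding
provider. The fixtures make every downstream claim testable against ground
truth.

## Quick start

The `pgccscreen` CLI runs the whole pipeline from a YAML config:

```yaml
# demo.yaml
output_dir: demo_run
seed: 7
n_plate_compounds: 4
n_compounds: 48
image_shape: [256, 256]
cv_rounds: 2
families: [Ridge, SVM, DT]
feature_set_ids: [MACCS, ECFP6, embedding-small]
vscreen_n_compounds: 20
top_k: 3
```

```text
$ pgccscreen run-all --config demo.yaml
... INFO stage simulate finished in 0.4s
... INFO stage quantify finished in 0.4s
... INFO stage screen-summary finished in 0.0s
... INFO stage features finished in 0.4s
... INFO stage benchmark finished in 3.0s
... INFO stage ensemble finished in 0.2s
... INFO stage vscreen finished in 0.2s
```

Outputs land under `demo_run/`. The screen summary for this run:

```json
{"library_size": 4, "excluded": 0, "screened": 4, "unclassifiable": 0,
 "total_inhibited": 3, "pgcc_enriched": 0, "pgcc_reduced_2x": 3,
 "pgcc_reduced_10x": 0, "dual_inhibitor": 3}
```

the top of `benchmark_results.csv`:

```text
         config_id        kind  median_rho
DT|embedding-small description    0.882509
       Ridge|MACCS   structure    0.702417
         SVM|MACCS   structure    0.620233
```

the ensemble manifest (meta-learner on the two best bases):

```json
{"base_structure": "Ridge|MACCS", "base_description": "DT|embedding-small",
 "median_rho": {"structure": 0.702, "description": 0.883, "ensemble": 0.837},
 "meta_coefficients": {"intercept": 0.107,
                       "beta_structure": 0.462, "beta_description": 0.625}}
```

and the ranked virtual-screen shortlist (`vscreen_top.csv`):

```text
compound_id                 smiles  predicted_y  rank
   EXT00012            CCCC1CCNCC1    -2.909689     1
   EXT00014 CSCCNCCNc1ccc2ccccc2c1    -2.049138     2
   EXT00016 CC(C)CCCc1ccncc1C(=O)N    -1.748750     3
```

Individual stages are available as subcommands (`simulate`, `quantify`,
`screen-summary`, `features`, `benchmark`, `ensemble`, `vscreen`); each runs
the stages it depends on and writes a `run_manifest.json` recording the
config hash, stage status and output paths.

## Library use

```python
from pgccscreen import fixtures as fx, imaging

img, truth = fx.generate_plate_image(n_nonpgcc=12, n_pgcc=3, n_dead=2, seed=7)
counts = imaging.quantify_well(img, fx.default_segmentation_params())
assert (counts.n_pgcc, counts.n_dead) == (truth.n_pgcc, truth.n_dead)
```

Each module is importable on its own: `imaging`, `screening`, `features`,
`models`, `ensemble`, `vscreen`, `fixtures`, `pipeline`.

## Tests and reproduction

```bash
python -m pytest -q tests/            # full suite, ~15-20 min on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` regenerates all synthetic data from the seed and
recomputes the headline quantities end to end — imaging count recovery, the
screen-category brute-force agreement, planted-SAR signal recovery and the
permuted-response null, the full 63-configuration benchmark, ensemble
statistics and virtual-screen ranking quality — writing each as
`{"value": ..., "n": ...}` JSON. It takes roughly 15 minutes on one CPU.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and the limits of the synthetic fixtures.
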