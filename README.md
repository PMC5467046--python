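# pssmbind

PSSM-based prediction of peptide binding affinity to HLA class I alleles.

`pssmbind` trains a position-specific scoring matrix (PSSM) per
(allele, peptide-length) pair from sets of known binder peptides, scores
peptides by mean log-odds lookup, and converts binding scores into
nanomolar IC50 values (`IC50 = 50000^((Max - score)/(Max - Min))`, Max 0.8,
Min -0.8 by default). Peptides with IC50 < 500 nM are classified as
binders, < 50 nM as strong binders.

Alleles without training data are predicted **pan-specifically**: each is
paired with every characterized allele, weighted by the BLOSUM62
local-alignment score of their protein sequences, and its IC50 is the
weighted mean of the neighbors' allele-specific IC50s.

The package also provides:

* **training_io** — training-table parsing with the cleaning rules
  (non-standard residues B/J/O/U/X/Z dropped, exact duplicates removed,
  lengths restricted to 8-25, at least 10 binders per (allele, length)).
* **evaluation** — seeded k-fold cross-validation with
  background-sampled nonbinders, Mann-Whitney AUC, and accuracy /
  sensitivity / specificity at the 500 nM cutoff.
* **neoantigen** — enumeration of mutant 8-13mer windows from
  protein-level somatic mutations and the two-condition neoantigen filter
  (mutant IC50 < 500 nM, and strictly below the wild-type IC50 for
  substitutions).
* **synthetic_fixtures** — seeded generators for planted-motif binder
  sets, background peptides and families of near-identical synthetic HLA
  protein sequences, so everything is testable offline.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance-criteria suite (analytic
transform identities, metric-oracle equivalence, planted-motif recovery,
pan-specific consistency, weighted-mean properties, window-enumeration
oracle, and seed stability).

## Command line

```sh
# synthetic demo data (training TSV, HLA FASTA, mutation TSV)
pssmbind simulate --out demo --seed 1

# train a PSSM library
pssmbind train --training demo/training.tsv --out library --seed 1

# allele similarity weights for pan-specific prediction
pssmbind similarity --hla-fasta demo/hla.fasta --library library --out sim.tsv

# predict (allele-specific if the allele has a PSSM, else pan-specific)
pssmbind predict --peptides peps.txt --allele HLA-A*01:01 \
    --library library --out predictions.tsv
pssmbind predict --peptides peps.txt --allele HLA-B*01:01 \
    --library library --similarity sim.tsv --out predictions.tsv

# 10-fold cross-validation
pssmbind cv --training demo/training.tsv --out cv_out --seed 1

# neoantigen candidates
pssmbind neoantigen --proteins demo/proteins.fasta \
    --mutations demo/mutations.tsv --alleles HLA-A*01:01 \
    --library library --out neo_out
```

Every subcommand echoes its configuration to `run_config.json` and writes
a `run.log` (package version, seed, input checksums) into its output
directory; re-running an echoed config reproduces outputs bit-for-bit.

## File formats

* **Training TSV** — columns `allele`, `peptide`, optional `label`
  (`binder`/`nonbinder`, default binder) and `source`.
* **PSSM file** — one per (allele, length): `#allele=`, `#length=`,
  `#log_base=`, `#omega=<mode:value:seed>`, `#n_binders=` headers followed
  by 20 tab-separated amino-acid rows (6 significant digits); a library
  directory carries a `manifest.tsv`.
* **Similarity TSV** — `uncharacterized_allele`, `characterized_allele`,
  `weight`, `source` (`alignment` or `nearest_distance`).
* **Mutation TSV** — `protein_id`, `position` (1-based), `kind`
  (`substitution`/`insertion`/`deletion`), `ref_aa`, `alt_aa`.
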