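"""Generate a synthetic multi-cancer cohort with planted driver genes.

The generator emulates the structure the scoring pipeline assumes: per-cancer
expression signatures with a copy-number dosage effect, focal driver
amplifications/deletions on a background of random segments, elevated and
positionally clustered mutations in driver genes, a clonal/subclonal CCF
mixture, and rare tiered fusions.
"""

import panrec

spec = panrec.default_spec(seed=1, n_cancer_types=2, samples_per_type=60)
bundle, truth = panrec.generate_cohort(spec)

print(f"cancer types: {bundle.cancer_types}")
print(f"samples: {len(bundle.samples)}, segments: {len(bundle.segments)}, "
      f"mutations: {len(bundle.mutations)}, fusions: {len(bundle.fusions)}")
for ct in bundle.cancer_types:
    print(f"{ct}: planted amplified {sorted(truth.amplified[ct])}, "
          f"deleted {sorted(truth.deleted[ct])}, "
          f"mutated {sorted(truth.mutated[ct])}")
# Each planted (gene, cancer) pair is the ground truth that the SCNA filter,
# the mutation index, and the integrated ranking are expected to recover.
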