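"""Type every gene and tumor into the three focal-amplification classes.

A gene is 'circular' when it is focally amplified (CN >= max(5, 2.25 x
ploidy)) AND its cargo probability clears the cutoff; focally amplified
genes below the cutoff are 'noncircular'; everything else is 'nofocal'.
A tumor inherits the strongest class among its genes, and its circular
genes become the predicted ecDNA cargo.
"""

from focalamp import classifier as clf
from focalamp import focal_typing as ft
from focalamp.cohort_stats import cohort_summary
from focalamp.feature_engineering import build_feature_matrix
from focalamp.simulate import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_samples=40, n_genes=150, seed=11))
matrix = build_feature_matrix(cohort.profiles, cohort.genes, cohort.priors)
table = matrix.merge(
    cohort.truth[["sample_id", "gene_id", "is_cargo"]], on=["sample_id", "gene_id"]
)
table["label"] = table["is_cargo"].astype(int)
model = clf.train(table, clf.ModelConfig(k_folds=4, n_search=5, seed=11))

probs = clf.predict_gene_prob(model, table)
gene_calls = ft.call_genes(probs, table, p_cut=model.p_cut)
sample_calls = ft.call_cohort(gene_calls)

summary = cohort_summary(sample_calls)
for klass in ("circular", "noncircular", "nofocal"):
    print(f"{klass:<12} {summary[klass]['count']:>3}  ({summary[klass]['percent']}%)")

circ = [sc for sc in sample_calls if sc.klass == "circular"]
if circ:
    sc = circ[0]
    print(f"example ecDNA+ tumor {sc.sample_id}: cargo genes {list(sc.cargo_genes)}")
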