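"""Relative feature importance across developmental stages.

Trains a random forest on an expression-driven term whose planted signal
sits at time-points 14-16 (the larval stage), computes the collapsed
per-time-point RFI profile and the per-stage maxima, and applies the 0.7
relevance screen.
"""

import numpy as np

from funcfly.classifier_bank import ClassifierSpec
from funcfly.dataset_builder import (
    build_term_dataset,
    propagate_annotations,
    split_train_test,
)
from funcfly.expression_features import compose_feature_group, gene_to_protein_features
from funcfly.importance import expression_profile, forest_importance, high_relevance_terms
from funcfly.synthetic_data import (
    BenchmarkConfig,
    PlantedTermSpec,
    generate_benchmark,
)

config = BenchmarkConfig(
    n_genes=300,
    n_seq_features=100,
    terms=(PlantedTermSpec(namespace="BP", driver="expression", n_positives=80,
                           informative_timepoints=(14, 15, 16)),),
    seed=12,
)
bench = generate_benchmark(config)
expr_feats = gene_to_protein_features(bench.expression)
matrix = compose_feature_group(
    [bench.seq_features, expr_feats], ("Seq", "Num", "Ave", "Main")
)
propagated = propagate_annotations(bench.annotations, bench.dag)
term = next(iter(bench.manifest.terms))
dataset = split_train_test(build_term_dataset(term, matrix, propagated, bench.dag),
                           seed=0)

forest = ClassifierSpec("RF", (("n_estimators", 300),)).build(seed=0)
forest.fit(dataset.X_train, dataset.y_train)
fi = forest_importance(forest, feature_names=matrix.feature_names)
profile = expression_profile(term, fi, matrix.groups.to_dict())

peak = int(np.argmax(profile.rfi_timepoint)) + 1
print(f"term {term}: planted signal at time-points 14-16 (larva)")
print(f"collapsed RFI profile peak: T{peak} "
      f"(RFI={profile.rfi_timepoint.max():.3f})")
for stage, value in profile.rfi_stage.items():
    print(f"  stage {stage:<6} max RFI = {value:.3f}")
screened = high_relevance_terms([profile], threshold=0.7)
print(f"passes the 0.7 expression-relevance screen: {term in screened}")

# The RFI profile compares each expression feature's forest importance to
# the global and expression-local maxima; the larval stage should carry the
# peak (RFI near 1.0) while the other stages stay near the noise floor.
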