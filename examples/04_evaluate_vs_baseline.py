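"""Compare the combined method with the correlation-only baseline.

The baseline predicts the top-K |PCC| pairs with K matched to the combined
method's prediction count, so the comparison is count-for-count fair.  Two
readouts: how many curated seed pairs each method recovers (with a
hypergeometric over-representation p), and the gene-level ROC AUC of the
fused centrality score vs the best-|PCC|-per-gene score.
"""

from crgnet.evaluation import compare_with_baseline
from crgnet.network_filter import centrality_profile
from crgnet.pipeline import run_pipeline
from crgnet.rank_fusion import fuse_gene_ranks
from crgnet.synthetic_data import FixtureSpec, generate_fixture_bundle

bundle = generate_fixture_bundle(FixtureSpec(rng_seed=1))
result = run_pipeline(
    bundle.expression, bundle.activity, bundle.network,
    bundle.annotation, bundle.ontology, bundle.compendium,
    characterize=False,
)

profile = centrality_profile(bundle.network)
fusion = fuse_gene_ranks(
    profile, [g for g in bundle.expression.index if g in profile.index]
)
scores = dict(zip(fusion["gene"], -fusion["q_score"]))
rep = compare_with_baseline(
    result.predictions, result.edges, bundle.compendium,
    combined_gene_scores=scores,
)

print(f"matched prediction count K = {rep['k']}")
print(f"combined filters : {rep['combined'].n_hit}/{rep['combined'].m} seed pairs, "
      f"p = {rep['combined'].p:.3g}")
print(f"|PCC| baseline   : {rep['baseline'].n_hit}/{rep['baseline'].m} seed pairs, "
      f"p = {rep['baseline'].p:.3g}")
print(f"gene-level AUC   : combined {100 * rep['combined_roc'].auc:.1f}%  "
      f"vs baseline {100 * rep['baseline_roc'].auc:.1f}%")
print(
    "\nThe combined method ranks seed genes higher because most planted\n"
    "correlations are weak (|r| < 0.3): correlation alone misses them,\n"
    "while their hub/bottleneck network position still gives them away."
)
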