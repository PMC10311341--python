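"""Quantify how planted cross-family similarity degrades family prediction.

Builds interaction-mode features for three families — ILE and ILF (which
share planted structure in half their instances) and ILC (unrelated) — and
evaluates one-vs-rest Gaussian naive Bayes classifiers with undersampling
and repeated stratified 3-fold cross-validation.
"""

from motifcompare import (
    PipelineConfig,
    build_features,
    default_family_specs,
    default_planted,
    evaluate_binary,
    evaluate_multiclass,
    generate_corpus,
    load_corpus,
    select_representative,
)
from motifcompare.pipeline import compute_pair_records

manifest = generate_corpus(
    default_family_specs(n_instances=10), default_planted(),
    seed=11, out_dir="example_corpus_full",
)
config = PipelineConfig(modes=("interaction",),
                        family_filter={"ILC", "ILE", "ILF"})
motifs, _, ann = load_corpus(
    manifest.locations_path, manifest.structures_dir, manifest.annotations_dir,
    config.family_filter,
)
records = compute_pair_records(motifs, ann, "interaction", config)
families = {}
for mid, m in sorted(motifs.items()):
    families.setdefault(m.family, []).append(mid)
reps = {
    fam: select_representative(
        fam, ids, [r for r in records if r.is_intra() and r.family_a == fam]
    ).motif_id
    for fam, ids in families.items()
}
X, y = build_features(motifs, reps, "interaction", ann)
print(f"feature table: {X.shape[0]} motifs x {X.shape[1]} features "
      f"(5 per representative family)")
for fam in sorted(families):
    rep = evaluate_binary(X, y, fam, seed=11)
    print(f"  {fam}: accuracy {rep.mean_accuracy:5.1f}%  "
          f"sensitivity {rep.mean_sensitivity:5.1f}%  "
          f"specificity {rep.mean_specificity:5.1f}%")
mc = evaluate_multiclass(X, y, seed=11)
print(f"  multiclass accuracy {mc.mean_accuracy:.1f}%")
# The unrelated family (ILC) is predicted near-perfectly, while the two
# families that share planted structure confuse their classifiers - the same
# qualitative pattern the similarity graph predicts.
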